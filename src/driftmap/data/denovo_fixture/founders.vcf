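##fileformat=VCFv4.2
##source=synthetic fixture (hand-constructed founder variant set; not real data)
##contig=<ID=chr1,length=100000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chr1	35000	.	C	T	99	PASS	DP=60
chr1	50000	.	G	T	99	PASS	DP=70
chr1	70000	.	T	A	99	PASS	DP=55
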