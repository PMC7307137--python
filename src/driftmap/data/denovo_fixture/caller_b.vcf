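##fileformat=VCFv4.2
##source=synthetic fixture (hand-constructed caller B call set; not real data)
##contig=<ID=chr1,length=100000>
##FILTER=<ID=lowQ,Description="Below quality threshold">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele read count">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chr1	15000	.	T	C	90	PASS	DP=28;AO=18
chr1	25000	.	A	T	90	PASS	DP=14;AO=7
chr1	35000	.	C	T	90	PASS	DP=38;AO=19
chr1	40000	.	T	G	90	PASS	DP=12;AO=9
chr1	45000	.	A	G	90	PASS	DP=16;AO=7
chr1	50000	.	G	A	90	PASS	DP=95;AO=55
chr1	55000	.	A	G	90	PASS	DP=40;AO=20
chr1	60000	.	G	T	90	PASS	DP=13;AO=8
chr1	65000	.	C	G	90	PASS	DP=75;AO=35
chr1	70000	.	T	A	90	PASS	DP=22;AO=11
chr1	85000	.	C	A	90	PASS	DP=32;AO=21
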