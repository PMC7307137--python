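##fileformat=VCFv4.2
##source=synthetic fixture (hand-constructed caller A call set; not real data)
##contig=<ID=chr1,length=100000>
##FILTER=<ID=lowQ,Description="Below quality threshold">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele read count">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chr1	15000	.	T	C	99	PASS	DP=30;AO=20
chr1	25000	.	A	T	99	PASS	DP=15;AO=8
chr1	30000	.	G	C	99	PASS	DP=50;AO=30
chr1	35000	.	C	T	99	PASS	DP=40;AO=20
chr1	40000	.	T	G	99	PASS	DP=10;AO=8
chr1	45000	.	A	G	99	PASS	DP=15;AO=6
chr1	50000	.	G	A	99	PASS	DP=100;AO=60
chr1	55000	.	A	C	99	PASS	DP=44;AO=22
chr1	60000	.	G	T	99	PASS	DP=11;AO=7
chr1	65000	.	C	G	12	lowQ	DP=80;AO=40
chr1	70000	.	T	A	99	PASS	DP=25;AO=12
chr1	85000	.	C	A	99	PASS	DP=30;AO=20
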