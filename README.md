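# driftmap

Selection mapping in multiparental pooled yeast populations.

`driftmap` analyses evolve-and-resequence (E&R) experiments in which a
heterogeneous *Saccharomyces cerevisiae* pool — millions of recombinant
haploid segregants intercrossed from the four founder strains NA (North
American), SA (Sake), WA (West African) and WE (Wine/European) — is grown
under a selective condition (a nitrogen-limited synthetic must, SM60) and a
control condition (nitrogen-sufficient, SM300), and sequenced as a pool at
three time points: before selection (T0), at the end of a batch phase (T1)
and after steady state in a chemostat (T2).  It is written for geneticists
and fermentation scientists who want to map the loci, expression changes
and genome-level events (de novo mutations, mitochondrial loss,
aneuploidies) that drive adaptation in such designs, and for methodologists
who want to test the scan statistics against simulations with planted
truth.

## What it computes

**Parental allele frequencies.**  At every segregating site the founder
marker table says which allele each founder carries.  Sites where one
founder is *private* (its allele differs from the other three) identify
that founder directly, so parent *j*'s frequency in window *i* is the
depth-weighted mean of private-allele read fractions over the private-*j*
sites in the window (10 kb windows every 2 kb), renormalized so that
Σ_j x_ij = 1.

**z-score QTL scan.**  For each window, parent, replicate and time point,

    Δx_ij(t) = x_ij(t) − x_ij(0),      z = (Δx_ij − μ_Δx) / σ_Δx,

with μ, σ taken over all windows, parents and replicates of a condition at
that time point.  A window is a QTL when one parent's z² exceeds the
empirical 99% (strong) or 95% (weak) quantile at both T1 and T2 in every
selected replicate, the replicate-mean z̄² increases from T1 to T2, and the
same window does not pass the control condition's own cut-offs.
Significant windows merge into intervals with a peak window and a favored
parent.

**ANOVA QTL scan.**  One-way ANOVA on arcsin-√-transformed frequencies
with time point as factor, Benjamini–Hochberg adjusted; windows whose
−log10(p_adj) exceeds the genome-wide 99% quantile in the treatment but
not in the control are QTLs.

**De novo mutations.**  Calls made by two independent callers
(intersected on chrom/pos/ref/alt, filter-passing only), minus the
founders' pre-existing variation, kept only at loci with >10 total and
>6 alternate reads, outside repeat-rich chromosome ends.

**Coverage diagnostics.**  Non-overlapping 10-kb depth windows feed an
aneuploidy screen (median-normalized chromosome depth), the
mitochondrial/nuclear depth-ratio time course (mtDNA copy number proxy)
and a clonal-expansion check (each parent's genome-wide mean frequency
should sit at 0.25 in a balanced pool).

**Expression and growth.**  Differentially expressed gene sets at
|log2 ratio| ≥ 2 (or ≥ 3) with confidence −log10 p_adj ≥ 2; parent-of-origin
attribution with a χ² test against the uniform 25% expectation;
parent-specific expression alleles outside the pooled 5%/95% quantiles;
Gompertz growth-curve fits y(t) = A·exp(−exp(μe/A(λ−t)+1)) giving lag λ,
rate μ and efficiency A, compared across groups by Welch t-tests; batch
μmax as the steepest sliding-window slope of ln(OD).

**Synthetic experiments.**  `driftmap.simulate` generates the whole design
with planted truth — intercrossed founder pool, chemostat selection at
chosen loci, overdispersed pooled sequencing, parent-biased expression,
mitochondrial depth decay and Gompertz growth curves — so every stage is
testable without external data.

## Worked example

Simulate a pool with one locus under selection (s = 0.2 per generation for
the NA allele at chr2:500250), estimate frequencies and run both scans:

```python
from driftmap import (SimConfig, QTL, simulate_experiment,
                      window_frequencies, ZScoreScan, AnovaScan)
from driftmap.frequency import mean_parent_frequency

conf = SimConfig(n_chromosomes=3, chrom_length=1_000_000, marker_spacing=500,
                 pop_size=1000, coverage=100, seed=7,
                 qtls=[QTL("chr2", 500_250, "NA", 0.2)])
bundle = simulate_experiment(conf)
track = window_frequencies(bundle.counts, bundle.founders.table,
                           chrom_lengths=bundle.founders.chrom_lengths)
print(mean_parent_frequency(track, "SM60_R1_T0")[0].round(3).to_dict())
print(ZScoreScan(track).fit().summary())
```

Output:

```
{'NA': 0.27, 'SA': 0.243, 'WA': 0.234, 'WE': 0.252}
zscore scan: 2 QTL interval(s)
  ...
  chr2:454000-516000 [strong] score=35.284 parent=NA peak=506000-516000
  chr2:522000-552000 [weak] score=17.363 parent=NA peak=522000-532000
```

The T0 means sit near 0.25 per parent — no clonal expansion in the
starting pool.  The strong interval covers the planted locus and names the
planted parent; its score is the peak replicate-mean z² at T2.  The ANOVA
scan re-captures the same region (`AnovaScan(track).fit().summary()`
reports chr2:454000-516000 with −log10 p_adj = 2.31), plus a handful of
weak flanking intervals driven by hitchhiking of linked windows.

The same stages are available from the shell:

```bash
driftmap simulate --config sim.yaml --out run/ --seed 7
driftmap freqs --markers run/markers.tsv --counts run/counts.tsv --out run/track.tsv
driftmap qtl-zscore --track run/track.tsv --out run/qtl.bed
driftmap denovo --caller-a a.vcf --caller-b b.vcf --founders founders.vcf \
                --exclude ends.bed --out denovo.vcf
driftmap run-all --config run.yaml
```

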