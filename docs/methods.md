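# Methods

This note documents the models, estimators and numerical choices behind
`driftmap`, in the order data flows through the package.

## The generative model

**Founder genome.**  A desk-scale genome of `n_chromosomes` × `chrom_length`
(default 6 × 2 Mb) carries segregating markers every `marker_spacing` bp.
Each marker is assigned an informativeness class: *private* to one of the
four founders with probability 0.80, a 2–2 *split* between founder pairs
with probability 0.15, otherwise a tri-allelic *other* pattern.  Real
four-founder yeast pools segregate roughly one site per 200 bp; the default
2-kb spacing keeps the default genome at 6 000 markers, and scenarios that
need dense within-window support (QTL recovery, calibration) set the
spacing to 500 bp.

**Intercross.**  The pool starts as equal numbers of the four founder
haplotypes and is intercrossed for 12 generations of random pairing
(selfing excluded) with Poisson(1) crossovers per chromosome per meiosis,
placed uniformly — approximately one obligate crossover, which is the right
scale for yeast chromosomes at desk size.  Every marker's parental dosage
has expectation 0.25 throughout.  The emulated population contains
10–100 million segregants, so intercross drift in the real experiment is
negligible; at a literal desk census of 2 000 it is not (per-locus σ ≈ 0.03
after 12 generations).  `SimConfig.intercross_census` therefore lets the
intercross run at a larger census (10 000 in the calibrated scenarios)
from which the `pop_size` analyzed haplotypes are sampled — mirroring how
such pools are actually constructed and carried.

**Selection phases.**  Propagation is asexual.  Generations per phase
follow the chemostat identity g = D·t/ln 2 (at steady state the growth
rate equals the dilution rate D); the batch phase uses the measured batch
growth rate the same way (defaults: 0.13 h⁻¹ for 24 h ≈ 5 generations,
then D = 0.10 h⁻¹ for 46 h ≈ 7 generations), rounded to whole generations.
Fitness is haploid and additive across planted loci,
w = 1 + Σ_k s_k·[carries the favored parent at locus k], applied in the
treatment only.  Two propagation modes exist:

* `apply_drift=True` (default): Wright–Fisher multinomial resampling of N
  individuals per generation — finite-N drift at desk scale.
* `apply_drift=False`: the infinite-census limit.  The N sampled haplotypes
  form a fixed library whose relative weights evolve deterministically as
  w^g; under neutrality frequencies are constant over time.  This is the
  faithful emulation of a 10⁷–10⁸-cell culture, where neutral drift over
  ~12 generations is orders of magnitude smaller than sequencing noise,
  and it is the mode used for the neutral-calibration and clonality
  scenarios.

**Pooled sequencing.**  Per site, total depth ~ Poisson(coverage); allele
counts follow a multinomial (ρ = 0) or Dirichlet-multinomial (ρ > 0) over
the site's allele partition — each allele's probability is the summed
frequency of the founders carrying it.  The default overdispersion
ρ = 0.01 reflects that pool-seq counts exceed binomial variance; for a
two-allele site at fixed depth n the count-fraction variance is
p(1−p)(1+(n−1)ρ)/n.

**Side channels.**  The DE-table generator plants 111 down- and
76 up-regulated genes passing |log2 ratio| ≥ 2 with confidence ≥ 2 (26 and
24 of which also pass ≥ 3) over a background of null genes; up-regulated
genes draw parent-of-origin reads biased toward one founder (default NA,
weight 0.55).  Expression-allele frequencies per replicate include a
configurable number of consistently biased outlier genes (≈ 0.99 for the
biased parent) over Beta(10, 30) noise centred near 0.25.  Mitochondrial
window depth starts at `mito_base_ratio` × nuclear coverage and decays by
`mito_loss_per_gen` (default 10%) per realized generation in the treatment
only.  Growth curves are Zwietering–Gompertz with configurable (A, μ, λ)
and optional Gaussian noise.  One `numpy` Generator drives everything in a
fixed stream order (founders → intercross → selection by condition, then
replicate, then phase → counts in sample order → expression → depth →
growth), so a seed reproduces all outputs bit-for-bit.

## Frequency estimation

Only private-allele sites identify a single parent, so they alone feed the
estimates; 2–2 split sites are exposed as pair-sum consistency checks
(`site_parent_frequency`) and *other* sites are ignored.  Per 10-kb window
(2-kb step, 0-based half-open, flush final window when the length does not
divide evenly) and parent j, the estimate is the depth-weighted mean of
private-allele read fractions over private-j sites with non-zero depth —
depth weighting minimizes variance under near-binomial noise.  The four
per-parent estimates are renormalized to sum to 1.  A window is masked for
a sample when any parent has fewer than `min_markers` informative sites
(default 1: at realistic site densities a 10-kb window holds ~5–20 private
sites spread over four parents, so requiring one per parent is the tightest
default that leaves windows usable; raise it when sites are dense).  Zero
depth yields a missing value, never a zero frequency.  Coordinates are
0-based half-open internally and in BED output, 1-based in marker/count
TSVs; every file header states its convention.

## The z-score scan

Δx_ij(t) = x_ij(t) − x_ij(T0) per replicate.  Standardization pools all
(window, parent, replicate) triples of a condition at a time point —
a per-window σ from three replicates would be statistically unusable, and
empirical z² quantiles presuppose a genome-wide distribution.  σ is the
population (ddof = 0) standard deviation, which makes the identity
mean(z) = 0, sd(z) = 1 exact; σ = 0 raises a degenerate-scan warning and
zeroes the scan.  Quantiles are linear-interpolation empirical quantiles
and all threshold comparisons are strict (`>`).

The significance rule (default `replicate_rule="all"`): a window passes at
level q for parent j when **every** replicate's z² clears that time point's
q-quantile of the pooled per-replicate z² at both T1 and T2 — the same
parent at both time points — and the replicate-mean z̄² increases from T1
to T2.  The control filter removes windows that pass the control
condition's own quantiles at both time points (no increase requirement).
The per-replicate rule is the default because the z-score is computed per
population and replicates are independent: under neutrality the
probability that all three replicates clear the 99% cut-off at both time
points is ~10⁻⁶ per entry, so the scan stays calibrated even though
Δx(T1) and Δx(T2) share the T0 sample's sequencing noise (correlation
≈ 0.5, which defeats a replicate-mean rule by letting ~0.1% of windows
persist by chance).  `replicate_rule="mean"` (threshold on z̄² instead) is
available for sensitivity analyses.

Windows significant at the 99% rule merge into *strong* intervals,
remaining 95% windows into *weak* intervals (weak intervals overlapping a
strong one are absorbed).  Merging joins overlapping or book-ended
windows; the interval score is the peak replicate-mean z² at T2, the
favored parent the arg-max parent among those passing at the peak window
(ties reported in full, never broken silently) with the sign of its Δx.

## The ANOVA scan

Frequencies are clipped to [0, 1] (renormalization can leave ±1e-12
excursions) and transformed y = arcsin √x, the classical
variance-stabilizing transform for proportions.  Per (window, parent), a
one-way F-test with time point as the factor (3 groups × replicates; time
only — no replicate blocking) via `scipy.stats.f_oneway`; cells that are
entirely constant give F = 0, p = 1 (no evidence, not an error).  P-values
are Benjamini–Hochberg adjusted across all unmasked (window, parent) pairs
of a condition, scored as −log10(p_adj), and thresholded at the genome-wide
99% empirical quantile; the control filter is symmetric (the control's own
quantile).  Masking requires the window unmasked in all nine samples of
the condition.

## De novo variants

Filter-passing calls from two callers intersect on (chrom, pos, ref, alt),
with depth fields taken from caller A (configurable).  Founder subtraction
is allele-aware by default — a call at a founder position with a different
alternate allele is kept — switchable to position-only.  Depth thresholds
are strict: total > 10 and alternate > 6, so 10/8 and 15/6 are both
dropped.  Exclusion regions are sorted, merged, 0-based half-open
intervals; the default builder excludes 20 kb from each chromosome end,
the repeat-rich zone most prone to false positives.  Founder subtraction
and depth filtering are per-variant predicates, so the chain is
order-independent between them, and the output is always a subset of the
intersection.  A recurrence report flags variants seen in ≥ 2
replicas/time points, without attaching a significance claim.

## Coverage diagnostics

Depth windows are non-overlapping 10-kb means; trailing partial windows
keep their true span.  The aneuploidy screen normalizes each chromosome's
mean depth by the genome median of window depths (mito and user-excluded
contigs removed from "nuclear") and flags excursions outside [0.75, 1.25]:
in a pool, a full single-chromosome duplication shifts depth by the swept
fraction, so the band corresponds to ~25% sweeps.  The mito ratio is mean
mito depth / mean nuclear depth; a replica is called monotonically
decreasing only when each step T0→T1→T2 loses more than 5% of the ratio —
with three time points a strict ordering occurs by chance one time in six,
while Poisson depth noise stays below ~5% at 50× and genuine mitochondrial
loss (≈ 40–60% per phase at the default loss rate) far exceeds it.  The
clonality check passes when every parent's genome-wide mean frequency is
within 0.10 of the balanced 0.25 and otherwise names the offending parent.

## Expression analyses

DE selection applies both printed cut-offs inclusively: |log2 ratio| ≥
threshold (2 or 3) **and** confidence −log10 p_adj ≥ 2.  Parent-of-origin
is the arg-max of per-parent read counts; ties and all-zero rows are
*unassigned* and excluded from the distribution rather than fabricating an
origin.  The χ² test is Pearson's goodness-of-fit against (¼, ¼, ¼, ¼),
df = 3, no continuity correction (four cells).  The ASE rule flags
expression-allele frequencies strictly outside the pooled empirical 5%/95%
quantiles; fewer than 20 pooled entries is refused because the tail
quantiles would be unstable.  Cross-replica consistency is the exact
intersection of (gene, parent, sign) triples.

## Growth curves

The Zwietering reparameterized Gompertz y(t) = A·exp(−exp(μe/A(λ−t)+1))
expresses the fit directly in lag λ (h), rate μ (tangent slope at the
inflection, OD h⁻¹) and efficiency A.  Efficiency is reported net of the
first reading (baseline subtraction), since plate readers report medium
turbidity in the blank.  Fitting is nonlinear least squares from a
deterministic grid of 24 starting points (A from the maximum corrected OD
×{1, 1.2}; μ from the steepest finite difference ×{0.5, 1, 2}; λ from the
tangent intercept, halved, stretched, and zero), tolerance 1e-8, best
residual wins; non-convergence from every start is an error, as is a flat
curve.  Parameter uncertainties are the asymptotic standard errors from
the fit covariance.  Welch's t (Satterthwaite df) compares parameter
groups; μmax is the maximum slope of ln(OD) over a 5-point sliding
regression, skipping windows containing non-positive OD, with slopes below
1e-12 reported as exactly 0.

## Desk scales used by the shipped scenarios

* Neutral clonality / acceptance script: default genome (6 × 2 Mb, markers
  every 2 kb), intercross census 10 000, analyzed pool N = 2 000, 100×
  coverage, drift-free neutral propagation.  Expected per-parent deviation
  from 0.25 is ~0.015.
* Planted-QTL recovery: same genome at 500-bp marker spacing, N = 2 000,
  three loci at s = 0.2 per generation, ~5 batch + ~7 chemostat
  generations, 3 + 3 replicates, 100×.
* Neutral calibration: 200 seeds of a 2 × 500 kb genome at 500-bp spacing,
  N = 300, 50×, drift-free — small enough to rerun hundreds of times,
  dense enough that windows are unmasked.

## What the simulator does and does not emulate

It emulates the population-genetic and counting structure of the design:
recombinant founder mosaics, selection at chosen loci with linkage,
overdispersed pooled counts, replicate/time structure, treatment-only
mitochondrial depth loss, parent-biased expression and Gompertz growth.
It does **not** emulate read-level artifacts (mapping bias, PCR
duplicates, base errors), diploidy or dominance, mtDNA sequence evolution
(depth only), caller behaviour (de novo inputs are consumed as call sets),
batch-effect structure in expression, or inoculation physiology (batch
generations are a configured rate × duration).  Passing tests therefore
demonstrate that the estimators and scan rules are correct and calibrated
under the stated stochastic model — not that real reads, aligners and
callers introduce no additional biases.

## Known limitations

* Window frequency estimates use private sites only; where a parent has no
  private site in a window the window is masked rather than imputed.
* The favored-parent call is marginal per window; tightly linked QTLs of
  different parents merge into one interval with the stronger parent at
  the peak.
* The ANOVA control filter thresholds on the control's own score
  distribution; when the control has essentially no signal its 99%
  quantile is near zero and the filter removes ~1% of windows at random —
  harmless but worth knowing when counting intervals.
* Gompertz standard errors are asymptotic; for 30-minute sampling over
  48 h they are small, but they ignore autocorrelated plate-reader noise.
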