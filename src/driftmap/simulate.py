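"""Synthetic selection experiments with planted truth.

Emulates the SGRP-4X design at desk scale: four founder strains (NA, SA,
WA, WE) intercrossed for 12 generations into a recombinant haploid pool,
then propagated asexually through a batch phase and a nitrogen-limited
chemostat (treatment) or nitrogen-sufficient chemostat (control), with
selection acting at a few planted loci in the treatment only.  Pooled
sequencing is emulated as Poisson total depth with multinomial or
Dirichlet-multinomial (overdispersed) allele counts at every segregating
site.  Side channels emulate the rest of the study's data: a differential
expression table with parent-biased read attribution, window depth tracks
with progressive mitochondrial loss in the treatment, and Gompertz-shaped
microculture growth curves.

All randomness flows from a single :class:`numpy.random.Generator`; the
stream order is fixed (founders, intercross, selection by condition then
replicate then phase, counts in sample order, expression, depth, growth),
so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import PARENTS, TIMES, as_rng
from .markers import classify_markers

LN2 = math.log(2)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


# --------------------------------------------------------------------------
# configuration and truth containers


@dataclass(frozen=True)
class QTL:
    """A planted selected locus: must sit on a marker position."""

    chrom: str
    pos: int
    favored_parent: str
    s: float  # selection coefficient per generation, >= 0


@dataclass
class SimConfig:
    # genome
    n_chromosomes: int = 6
    chrom_length: int = 2_000_000
    marker_spacing: int = 2_000
    # population
    pop_size: int = 2_000
    intercross_generations: int = 12
    # census during the intercross; the analyzed pool of `pop_size`
    # haplotypes is sampled from it afterwards.  None -> intercross at
    # pop_size.  The emulated pool is built from 10-100 million segregants,
    # so a census well above pop_size keeps intercross drift negligible.
    intercross_census: int | None = None
    qtls: list[QTL] = field(default_factory=list)
    # culture phases; chemostat generations per hour = D/ln2, batch analogously
    batch_hours: float = 24.0
    continuous_hours: float = 46.0
    dilution_rate: float = 0.10  # h^-1
    batch_growth_rate: float = 0.13  # h^-1, mu_max of the pool in batch
    # sequencing
    coverage: float = 100.0
    overdispersion: float = 0.01  # beta-binomial intra-pool correlation rho
    # design
    replicates: int = 3
    # True: finite-N multinomial resampling each generation (desk-scale drift).
    # False: infinite-census limit — the pool of N sampled haplotypes is
    # treated as a library whose relative weights evolve deterministically
    # under selection (the emulated population has 10-100 million
    # segregants, so neutral drift over ~12 generations is negligible).
    apply_drift: bool = True
    treatment: str = "SM60"
    control: str = "SM300"
    # marker class mix
    p_private: float = 0.80
    p_split: float = 0.15
    # mitochondria (depth only)
    mito_chrom: str = "chrM"
    mito_length: int = 80_000
    mito_base_ratio: float = 10.0  # mito/nuclear depth ratio at T0
    mito_loss_per_gen: float = 0.10  # fractional loss per generation, treatment only
    # expression truth
    n_de_down: int = 111
    n_de_up: int = 76
    n_de_down_strict: int = 26
    n_de_up_strict: int = 24
    n_background_genes: int = 313
    expr_bias_parent: str = "NA"
    expr_bias_weight: float = 0.55
    expr_reads_per_gene: int = 200
    n_ase_outliers: int = 1
    # growth curves
    gompertz_A: float = 0.9
    gompertz_mu: float = 0.5
    gompertz_lag: float = 2.0
    growth_hours: float = 48.0
    growth_interval: float = 0.5
    growth_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate D must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.overdispersion < 1):
            raise ValueError("overdispersion rho must lie in [0, 1)")
        if self.expr_bias_parent not in PARENTS:
            raise ValueError(f"unknown parent {self.expr_bias_parent!r}")
        for q in self.qtls:
            if q.s < 0:
                raise ValueError(f"selection coefficient must be >= 0, got {q.s}")
            if q.favored_parent not in PARENTS:
                raise ValueError(f"unknown favored parent {q.favored_parent!r}")

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.treatment, self.control)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class FounderHaplotypes:
    """Founder alleles at every segregating marker plus genome geometry."""

    table: pd.DataFrame  # chrom, pos (1-based), NA, SA, WA, WE, class
    chrom_lengths: dict[str, int]

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def marker_index(self, chrom: str, pos: int) -> int:
        """Global row index of the marker at (chrom, pos); raises if absent."""
        sub = self.table.index[(self.table["chrom"] == chrom) & (self.table["pos"] == pos)]
        if len(sub) != 1:
            raise ValueError(f"no marker at {chrom}:{pos}")
        return int(sub[0])


@dataclass
class Population:
    """Haploid pool: per chromosome an (N, markers) matrix of founder indices."""

    ancestry: dict[str, np.ndarray]
    founders: FounderHaplotypes

    @property
    def size(self) -> int:
        return next(iter(self.ancestry.values())).shape[0]

    def frequencies(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Noise-free per-marker parental frequencies, shape (markers, 4)."""
        blocks = []
        for chrom in self.founders.table["chrom"].unique():
            anc = self.ancestry[chrom]
            if idx is not None:
                anc = anc[idx]
            f = np.stack([(anc == j).mean(axis=0) for j in range(len(PARENTS))], axis=1)
            blocks.append(f)
        return np.concatenate(blocks, axis=0)

    def frequencies_weighted(self, weights: np.ndarray) -> np.ndarray:
        """Frequencies of a pool where haplotype i has relative weight w_i."""
        wsum = weights.sum()
        blocks = []
        for chrom in self.founders.table["chrom"].unique():
            anc = self.ancestry[chrom]
            f = np.stack([(weights[:, None] * (anc == j)).sum(axis=0) / wsum
                          for j in range(len(PARENTS))], axis=1)
            blocks.append(f)
        return np.concatenate(blocks, axis=0)


@dataclass
class SampleCounts:
    """Site x allele read counts for one sequenced pool sample."""

    replicate: int
    condition: str
    time: str
    counts: pd.DataFrame  # chrom, pos, allele, count

    @property
    def sample_id(self) -> str:
        return f"{self.condition}_R{self.replicate}_{self.time}"


@dataclass
class SimTruth:
    """Everything needed to verify recovery downstream."""

    qtls: list[QTL]
    generations: dict[str, float]  # real generations per phase + realized ints
    freqs: dict[tuple[str, int, str], np.ndarray]  # (condition, replicate, time) -> (M, 4)
    de_genes: pd.DataFrame | None = None  # gene, direction, biased_parent, log2_ratio
    ase_outliers: list[str] = field(default_factory=list)
    mito_ratio: dict[tuple[str, str], float] = field(default_factory=dict)
    growth_params: tuple[float, float, float] | None = None  # (A, mu, lag)


# --------------------------------------------------------------------------
# chemostat arithmetic


def generations_in_phase(dilution_rate: float, duration_hours: float) -> float:
    """Doublings completed in a phase growing at rate D for `duration` hours.

    At chemostat steady state the population growth rate equals the dilution
    rate D, so generations = D * t / ln 2.  The same identity converts a
    batch-phase growth rate into batch generations.
    """
    if dilution_rate <= 0:
        raise ValueError("dilution rate must be positive")
    if duration_hours < 0:
        raise ValueError("duration must be non-negative")
    return dilution_rate * duration_hours / LN2


# --------------------------------------------------------------------------
# founder genome and intercross


def _build_founders(config: SimConfig, rng: np.random.Generator) -> FounderHaplotypes:
    rows = []
    class_choices = ["private", "split", "other"]
    p_other = max(0.0, 1.0 - config.p_private - config.p_split)
    probs = [config.p_private, config.p_split, p_other]
    lengths = {}
    for chrom in config.chrom_names:
        lengths[chrom] = config.chrom_length
        n = config.chrom_length // config.marker_spacing
        positions = config.marker_spacing // 2 + config.marker_spacing * np.arange(n)
        kinds = rng.choice(class_choices, size=n, p=probs)
        for pos, kind in zip(positions, kinds):
            a, b = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS))]
            alleles = {p: a for p in PARENTS}
            if kind == "private":
                alleles[PARENTS[rng.integers(0, 4)]] = b
            elif kind == "split":
                pair = rng.choice(4, size=2, replace=False)
                for j in pair:
                    alleles[PARENTS[j]] = b
            else:  # tri-allelic 1-1-2 pattern
                third = next(c for c in "ACGT" if c not in (a, b))
                order = rng.permutation(4)
                alleles[PARENTS[order[0]]] = b
                alleles[PARENTS[order[1]]] = third
            rows.append({"chrom": chrom, "pos": int(pos), **alleles})
    table = classify_markers(pd.DataFrame(rows))
    return FounderHaplotypes(table=table, chrom_lengths=lengths)


def _meiosis(anc: np.ndarray, p1: np.ndarray, p2: np.ndarray, pos0: np.ndarray,
             length: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized meiosis for one chromosome: Poisson(1) crossovers, uniform."""
    n = p1.shape[0]
    k = rng.poisson(1.0, n)
    start = rng.integers(0, 2, n)
    kmax = int(k.max()) if n else 0
    if kmax == 0:
        return anc[np.where(start == 0, p1, p2)]
    bp = rng.uniform(0, length, (n, kmax))
    bp[np.arange(kmax)[None, :] >= k[:, None]] = length  # pad beyond last marker
    bp.sort(axis=1)
    crossings = (bp[:, :, None] <= pos0[None, None, :]).sum(axis=1)
    parity = (crossings + start[:, None]) % 2
    return np.where(parity == 0, anc[p1], anc[p2])


def simulate_founder_pool(config: SimConfig,
                          rng: np.random.Generator | int | None = None,
                          ) -> tuple[FounderHaplotypes, Population]:
    """Intercross the four founders into a recombinant haploid pool.

    Generation 0 seeds the pool equally from the founders; each intercross
    round pairs random distinct parents and recombines with Poisson(1)
    crossovers per chromosome.  Every marker's expected parental dosage is
    0.25 per parent throughout.
    """
    if config.pop_size < 100:
        raise ValueError("pop_size < 100: drift would dominate unrealistically")
    n = config.intercross_census or config.pop_size
    if n < config.pop_size:
        raise ValueError("intercross_census must be >= pop_size")
    rng = as_rng(config.seed if rng is None else rng)
    founders = _build_founders(config, rng)
    ancestry = {}
    for chrom in config.chrom_names:
        m = (founders.table["chrom"] == chrom).sum()
        ancestry[chrom] = np.tile((np.arange(n) % 4).astype(np.int8)[:, None], (1, m))
    for _ in range(config.intercross_generations):
        p1 = rng.integers(0, n, n)
        p2 = rng.integers(0, n, n)
        clash = p1 == p2
        while clash.any():
            p2[clash] = rng.integers(0, n, int(clash.sum()))
            clash = p1 == p2
        for chrom in config.chrom_names:
            pos0 = founders.positions(chrom).astype(float) - 1.0
            ancestry[chrom] = _meiosis(ancestry[chrom], p1, p2, pos0,
                                       founders.chrom_lengths[chrom], rng)
    if n > config.pop_size:
        keep = rng.choice(n, config.pop_size, replace=False)
        ancestry = {c: a[keep] for c, a in ancestry.items()}
    return founders, Population(ancestry=ancestry, founders=founders)


# --------------------------------------------------------------------------
# selection phases


def _fitness(pop: Population, qtls: list[QTL]) -> np.ndarray:
    w = np.ones(pop.size)
    for q in qtls:
        sub = pop.founders.table
        row = sub.index[(sub["chrom"] == q.chrom) & (sub["pos"] == q.pos)]
        if len(row) != 1:
            raise ValueError(f"QTL at {q.chrom}:{q.pos} does not coincide with a marker")
        offset = int(row[0] - sub.index[sub["chrom"] == q.chrom][0])
        carrier = pop.ancestry[q.chrom][:, offset] == PARENTS.index(q.favored_parent)
        w = w + q.s * carrier
    return w


def simulate_selection_experiment(population: Population, config: SimConfig,
                                  rng: np.random.Generator | int | None = None,
                                  ) -> SimTruth:
    """Propagate the pool through batch + chemostat under both conditions.

    Asexual Wright-Fisher resampling: each generation draws N individuals
    multinomially with probability proportional to fitness
    w = 1 + sum_k s_k * [carries favored allele at QTL k] (treatment only;
    in the control all s are 0).  Noise-free parental frequencies are
    recorded at T0 (pre-selection), T1 (end of batch), T2 (end of chemostat).
    """
    rng = as_rng(config.seed + 1 if rng is None else rng)
    n = population.size
    g_batch = generations_in_phase(config.batch_growth_rate, config.batch_hours)
    g_chem = generations_in_phase(config.dilution_rate, config.continuous_hours)
    n_batch, n_chem = round(g_batch), round(g_chem)
    w = _fitness(population, config.qtls)
    freqs: dict[tuple[str, int, str], np.ndarray] = {}
    t0 = population.frequencies()
    for condition in config.conditions:
        selected = condition == config.treatment
        for rep in range(1, config.replicates + 1):
            freqs[(condition, rep, "T0")] = t0
            if config.apply_drift:
                idx = np.arange(n)
                for time, gens in (("T1", n_batch), ("T2", n_chem)):
                    for _ in range(gens):
                        if selected and config.qtls:
                            p = w[idx] / w[idx].sum()
                            idx = idx[rng.choice(n, n, p=p)]
                        else:
                            idx = idx[rng.integers(0, n, n)]
                    freqs[(condition, rep, time)] = population.frequencies(idx)
            else:
                # infinite-census limit: haplotype weights grow as w^g
                for time, total_gens in (("T1", n_batch), ("T2", n_batch + n_chem)):
                    if selected and config.qtls:
                        weights = w ** total_gens
                        freqs[(condition, rep, time)] = population.frequencies_weighted(weights)
                    else:
                        freqs[(condition, rep, time)] = t0
    return SimTruth(
        qtls=list(config.qtls),
        generations={"batch": g_batch, "chemostat": g_chem,
                     "batch_realized": n_batch, "chemostat_realized": n_chem},
        freqs=freqs,
    )


# --------------------------------------------------------------------------
# pooled sequencing counts


def _beta_binomial(depth: np.ndarray, p: np.ndarray, rho: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Counts of the focal allele; binomial at rho=0, beta-binomial otherwise."""
    k = np.zeros(depth.shape, dtype=np.int64)
    live = depth > 0
    if rho == 0:
        k[live] = rng.binomial(depth[live], p[live])
        return k
    interior = live & (p > 0) & (p < 1)
    a = p[interior] * (1 - rho) / rho
    b = (1 - p[interior]) * (1 - rho) / rho
    k[interior] = rng.binomial(depth[interior], rng.beta(a, b))
    k[live & (p >= 1)] = depth[live & (p >= 1)]
    return k


def pooled_counts_one_sample(freq: np.ndarray, founders: FounderHaplotypes,
                             coverage: float, rho: float,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Emit site x allele counts for one pool given true parental frequencies.

    Total depth per site is Poisson(coverage); allele counts follow a
    (Dirichlet-)multinomial over the site's allele partition — each allele's
    probability is the summed frequency of the parents carrying it.
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    table = founders.table
    m = len(table)
    if freq.shape != (m, len(PARENTS)):
        raise ValueError(f"freq must have shape ({m}, 4)")
    sums = freq.sum(axis=1)
    if np.any(np.abs(sums - 1) > 1e-6):
        raise ValueError("per-site frequencies must sum to 1")
    alleles = table[list(PARENTS)].to_numpy(dtype="U1")
    depth = rng.poisson(coverage, m)
    is_other = (table["class"] == "other").to_numpy()
    two = ~is_other

    site_idx = np.arange(m)
    a_first = alleles[:, 0]
    p_first = (freq * (alleles == a_first[:, None])).sum(axis=1)
    second_col = np.argmax(alleles != a_first[:, None], axis=1)
    a_second = alleles[site_idx, second_col]

    k1 = np.zeros(m, dtype=np.int64)
    k1[two] = _beta_binomial(depth[two], np.clip(p_first[two], 0, 1), rho, rng)

    recs: list[tuple[int, str, int]] = []
    recs.extend(zip(site_idx[two], a_first[two], k1[two]))
    recs.extend(zip(site_idx[two], a_second[two], depth[two] - k1[two]))
    for i in site_idx[is_other]:
        seen: list[str] = []
        for a in alleles[i]:
            if a not in seen:
                seen.append(a)
        probs = np.array([(freq[i] * (alleles[i] == a)).sum() for a in seen])
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        if depth[i] == 0:
            counts = np.zeros(len(seen), dtype=np.int64)
        elif rho == 0:
            counts = rng.multinomial(depth[i], probs)
        else:
            alpha = np.clip(probs, 1e-12, None) * (1 - rho) / rho
            counts = rng.multinomial(depth[i], rng.dirichlet(alpha))
        recs.extend(zip([i] * len(seen), seen, counts))

    out = pd.DataFrame(recs, columns=["site", "allele", "count"])
    out = out.sort_values(["site", "allele"], kind="stable").reset_index(drop=True)
    out.insert(0, "chrom", table["chrom"].to_numpy()[out["site"]])
    out.insert(1, "pos", table["pos"].to_numpy()[out["site"]])
    return out.drop(columns="site")


def emit_pooled_counts(freqs: dict[tuple[str, int, str], np.ndarray],
                       founders: FounderHaplotypes, config: SimConfig,
                       rng: np.random.Generator | int | None = None,
                       ) -> list[SampleCounts]:
    """Sequence every (condition, replicate, time) pool of a truth dict."""
    rng = as_rng(config.seed + 2 if rng is None else rng)
    samples = []
    for condition in config.conditions:
        for rep in range(1, config.replicates + 1):
            for time in TIMES:
                key = (condition, rep, time)
                if key not in freqs:
                    continue
                df = pooled_counts_one_sample(freqs[key], founders, config.coverage,
                                              config.overdispersion, rng)
                samples.append(SampleCounts(replicate=rep, condition=condition,
                                            time=time, counts=df))
    return samples


# --------------------------------------------------------------------------
# expression, depth and growth side channels


def emit_de_table(config: SimConfig, rng: np.random.Generator,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE results table with planted up/down gene sets at two cut-off tiers."""
    rows, truth = [], []
    gi = 0

    def _plant(n_total, n_strict, sign):
        nonlocal gi
        for i in range(n_total):
            gi += 1
            gene = f"G{gi:04d}"
            if i < n_strict:
                ratio = sign * rng.uniform(3.0, 6.0)
            else:
                ratio = sign * rng.uniform(2.0, 3.0 - 1e-6)
            conf = rng.uniform(2.0, 10.0)
            rows.append((gene, ratio, conf))
            truth.append((gene, "up" if sign > 0 else "down"))

    _plant(config.n_de_down, config.n_de_down_strict, -1)
    _plant(config.n_de_up, config.n_de_up_strict, +1)
    for _ in range(config.n_background_genes):
        gi += 1
        ratio = float(np.clip(rng.normal(0, 0.5), -1.9, 1.9))
        rows.append((f"G{gi:04d}", ratio, rng.uniform(0.0, 6.0)))
    de = pd.DataFrame(rows, columns=["gene", "log2_ratio", "neg_log10_padj"])
    truth_df = pd.DataFrame(truth, columns=["gene", "direction"])
    truth_df["biased_parent"] = np.where(truth_df["direction"] == "up",
                                         config.expr_bias_parent, "")
    return de, truth_df


def emit_parent_counts(de_truth: pd.DataFrame, config: SimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene reads attributable to each parent; up-set biased as planted."""
    w = config.expr_bias_weight
    bias_idx = PARENTS.index(config.expr_bias_parent)
    rows = []
    for rec in de_truth.to_dict("records"):
        probs = np.full(4, 0.25)
        if rec["direction"] == "up":
            probs = np.full(4, (1 - w) / 3)
            probs[bias_idx] = w
        counts = rng.multinomial(config.expr_reads_per_gene, probs)
        rows.append((rec["gene"], *counts))
    return pd.DataFrame(rows, columns=["gene", *PARENTS])


def emit_ase_frequencies(de_truth: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    """Expression-allele frequencies per replicate with planted consistent outliers."""
    genes = de_truth["gene"].tolist()
    outliers = genes[: config.n_ase_outliers]
    rows = []
    for rep in range(1, config.replicates + 1):
        for gene in genes:
            for parent in PARENTS:
                if gene in outliers and parent == config.expr_bias_parent:
                    f = rng.uniform(0.97, 0.995)
                else:
                    f = float(np.clip(rng.beta(10, 30), 0, 1))  # around 0.25
                rows.append((rep, gene, parent, f))
    return pd.DataFrame(rows, columns=["replicate", "gene", "parent", "freq"]), outliers


def emit_depth_tables(config: SimConfig, generations: dict[str, float],
                      rng: np.random.Generator,
                      ) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """10-kb window mean depths per sample, nuclear + mito contig.

    Mito mean depth decays by `mito_loss_per_gen` per generation in the
    treatment; the control ratio stays at `mito_base_ratio`.
    """
    window = 10_000
    gens_at = {"T0": 0.0, "T1": generations["batch_realized"],
               "T2": generations["batch_realized"] + generations["chemostat_realized"]}
    rows = []
    truth: dict[tuple[str, str], float] = {}
    for condition in config.conditions:
        for time in TIMES:
            ratio = config.mito_base_ratio
            if condition == config.treatment:
                ratio *= (1 - config.mito_loss_per_gen) ** gens_at[time]
            truth[(condition, time)] = ratio
            for rep in range(1, config.replicates + 1):
                sample = f"{condition}_R{rep}_{time}"
                for chrom in config.chrom_names:
                    for start in range(0, config.chrom_length, window):
                        mean = rng.poisson(config.coverage * window) / window
                        rows.append((sample, chrom, start, start + window, mean))
                for start in range(0, config.mito_length, window):
                    end = min(start + window, config.mito_length)
                    span = end - start
                    mean = rng.poisson(config.coverage * ratio * span) / span
                    rows.append((sample, config.mito_chrom, start, end, mean))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "mean_depth"])
    return df, truth


def gompertz(t: np.ndarray, a: float, mu: float, lag: float) -> np.ndarray:
    """Zwietering-parameterized Gompertz: A exp(-exp(mu e / A (lag - t) + 1))."""
    return a * np.exp(-np.exp(mu * np.e / a * (lag - t) + 1.0))


def emit_growth_curves(config: SimConfig, rng: np.random.Generator,
                       n_wells: int = 3) -> pd.DataFrame:
    """OD600 microculture curves sampled on a 30-min-style grid."""
    t = np.arange(0, config.growth_hours + 1e-9, config.growth_interval)
    rows = []
    for well in range(1, n_wells + 1):
        od = gompertz(t, config.gompertz_A, config.gompertz_mu, config.gompertz_lag)
        if config.growth_noise_sd > 0:
            od = np.clip(od + rng.normal(0, config.growth_noise_sd, t.shape), 0, None)
        for ti, oi in zip(t, od):
            rows.append((f"W{well}", float(ti), float(oi)))
    return pd.DataFrame(rows, columns=["well", "time_h", "od600"])


@dataclass
class SimBundle:
    """One complete synthetic experiment: inputs for every pipeline stage."""

    config: SimConfig
    founders: FounderHaplotypes
    counts: list[SampleCounts]
    truth: SimTruth
    depth: pd.DataFrame
    de_table: pd.DataFrame
    parent_counts: pd.DataFrame
    ase_freqs: pd.DataFrame
    growth: pd.DataFrame


def simulate_experiment(config: SimConfig,
                        seed: int | None = None) -> SimBundle:
    """Run the full generative model under one seed; the bundle carries truth."""
    if seed is not None:
        config = replace(config, seed=seed)
    rng = as_rng(config.seed)
    founders, pop = simulate_founder_pool(config, rng)
    truth = simulate_selection_experiment(pop, config, rng)
    counts = emit_pooled_counts(truth.freqs, founders, config, rng)
    de_table, de_truth = emit_de_table(config, rng)
    parent_counts = emit_parent_counts(de_truth, config, rng)
    ase_freqs, outliers = emit_ase_frequencies(de_truth, config, rng)
    depth, mito_truth = emit_depth_tables(config, truth.generations, rng)
    growth = emit_growth_curves(config, rng)
    truth.de_genes = de_truth
    truth.ase_outliers = outliers
    truth.mito_ratio = mito_truth
    truth.growth_params = (config.gompertz_A, config.gompertz_mu, config.gompertz_lag)
    return SimBundle(config=config, founders=founders, counts=counts, truth=truth,
                     depth=depth, de_table=de_table, parent_counts=parent_counts,
                     ase_freqs=ase_freqs, growth=growth)
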