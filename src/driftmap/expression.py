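"""Post-differential-expression analyses.

Consumes an upstream DE results table (gene, log2 expression ratio
treatment vs control, confidence = −log10 adjusted p) and parent-of-origin
read counts, and implements: threshold selection of up/down gene sets,
parent-of-origin attribution with a chi-square test against the balanced
25%-per-founder expectation, the 5%/95% pooled-quantile rule for
parent-specific expression alleles, and the cross-replica consistency
intersection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import PARENTS, empirical_quantile


def select_de_genes(de_table: pd.DataFrame, min_abs_log2: float = 2.0,
                    min_confidence: float = 2.0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(up, down) gene subsets at inclusive |log2 ratio| and confidence cut-offs."""
    conf = de_table["neg_log10_padj"] >= min_confidence
    up = de_table[(de_table["log2_ratio"] >= min_abs_log2) & conf]
    down = de_table[(de_table["log2_ratio"] <= -min_abs_log2) & conf]
    return up.reset_index(drop=True), down.reset_index(drop=True)


def assign_parent_of_origin(parent_counts: pd.DataFrame, genes,
                            ) -> pd.DataFrame:
    """Imposed parent per gene = argmax of parent-aligned read counts.

    Ties and all-zero rows are 'unassigned' and excluded from downstream
    distributions — an origin is never fabricated.
    """
    genes = list(genes)
    sub = parent_counts.set_index("gene").reindex(genes)
    if sub[list(PARENTS)].isna().any().any():
        missing = sub.index[sub[list(PARENTS)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing parent counts for genes: {missing}")
    rows = []
    for gene, rec in sub.iterrows():
        counts = rec[list(PARENTS)].to_numpy(dtype=float)
        best = counts.max()
        winners = [p for p, c in zip(PARENTS, counts) if c == best]
        imposed = winners[0] if (best > 0 and len(winners) == 1) else "unassigned"
        rows.append((gene, imposed, *counts.astype(int)))
    return pd.DataFrame(rows, columns=["gene", "imposed_parent", *PARENTS])


def origin_distribution(assignments: pd.DataFrame) -> pd.Series:
    """Counts of imposed parents over the 4 founders (unassigned excluded)."""
    assigned = assignments[assignments["imposed_parent"] != "unassigned"]
    return assigned["imposed_parent"].value_counts().reindex(PARENTS, fill_value=0)


def chisq_uniform(counts) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of 4 parent counts against (¼,¼,¼,¼).

    Returns (statistic, df=3, p) with p from the χ² survival function; no
    continuity correction.  Zero total is an error.
    """
    obs = np.asarray(list(counts), dtype=float)
    if obs.shape != (4,):
        raise ValueError("need counts for exactly 4 parents")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be >= 1")
    expected = np.full(4, total / 4)
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = 3
    return statistic, df, float(stats.chi2.sf(statistic, df))


def ase_quantile_flags(allele_freqs: pd.DataFrame, lo: float = 0.05,
                       hi: float = 0.95) -> pd.DataFrame:
    """Flag (gene, parent) expression-allele frequencies outside the pooled
    5%/95% empirical quantiles (strict inequalities).

    `allele_freqs` needs columns gene, parent, freq.  Fewer than 20 pooled
    entries is refused: the tail quantiles would be unstable.
    """
    freqs = allele_freqs["freq"].to_numpy(dtype=float)
    if freqs.size < 20:
        raise ValueError("need >= 20 (gene, parent) frequencies for stable quantiles")
    q_lo = empirical_quantile(freqs, lo)
    q_hi = empirical_quantile(freqs, hi)
    out = allele_freqs.copy()
    out["sign"] = np.where(out["freq"] > q_hi, "high",
                           np.where(out["freq"] < q_lo, "low", ""))
    flagged = out[out["sign"] != ""].reset_index(drop=True)
    flagged.attrs["q_lo"] = q_lo
    flagged.attrs["q_hi"] = q_hi
    return flagged[["gene", "parent", "freq", "sign"]]


def consistency_across_replicas(flags_per_replica: list[pd.DataFrame],
                                ) -> pd.DataFrame:
    """(gene, parent, sign) triples flagged in every replica (set intersection)."""
    if len(flags_per_replica) < 2:
        raise ValueError("need flags from >= 2 replicas")
    sets = [set(map(tuple, df[["gene", "parent", "sign"]].to_numpy()))
            for df in flags_per_replica]
    common = sorted(set.intersection(*sets))
    return pd.DataFrame(common, columns=["gene", "parent", "sign"])
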