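"""Founder marker tables: site classification and per-site parental frequencies.

A segregating site is informative about a single founder only when that
founder carries a *private* allele (the other three founders share one
allele).  2-2 split sites constrain pair sums and serve as consistency
checks; sites with three or more alleles, or any other pattern, are labelled
``other`` and excluded from frequency estimation.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from ._util import PARENTS

#: marker classes
CLASS_OTHER = "other"


def classify_site(alleles: dict[str, str]) -> str:
    """Classify one site from its parent -> allele mapping.

    Returns ``private-P`` when parent P alone carries a distinct allele,
    ``split-2-2`` when two parent pairs each share an allele, ``other``
    for tri-/tetra-allelic patterns.  Raises if fewer than 4 parents or
    the site is not segregating.
    """
    if set(alleles) != set(PARENTS):
        raise ValueError(f"need alleles for exactly the 4 parents {PARENTS}, got {sorted(alleles)}")
    counts = Counter(alleles[p] for p in PARENTS)
    if len(counts) == 1:
        raise ValueError("site is not segregating (all founders share one allele)")
    if len(counts) == 2:
        sizes = sorted(counts.values())
        if sizes == [1, 3]:
            singleton = next(a for a, n in counts.items() if n == 1)
            parent = next(p for p in PARENTS if alleles[p] == singleton)
            return f"private-{parent}"
        return "split-2-2"
    return CLASS_OTHER


def classify_markers(table: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``class`` column to a founder marker table.

    `table` needs columns ``chrom``, ``pos`` (1-based) and one allele column
    per parent (NA, SA, WA, WE).  Positions must be strictly increasing per
    chromosome.
    """
    missing = [c for c in ("chrom", "pos", *PARENTS) if c not in table.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    for chrom, sub in table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions not strictly increasing on {chrom}")
    out = table.copy()
    out["class"] = [
        classify_site({p: row[p] for p in PARENTS}) for row in table.to_dict("records")
    ]
    return out


def private_allele(row) -> str:
    """The informative allele of a private-P site (row must carry 'class')."""
    cls = row["class"]
    if not cls.startswith("private-"):
        raise ValueError(f"not a private site: class={cls}")
    return row[cls.split("-", 1)[1]]


def site_parent_frequency(allele_counts: dict[str, int], row) -> dict[str, float]:
    """Partial parental frequencies at one classified site.

    For a private-P site returns ``{P: k/depth}`` where k counts reads with
    the private allele.  For a split-2-2 site returns the two pair-sum
    frequencies keyed ``"P1+P2"``.  Zero depth yields NaN (missing), never 0.
    """
    cls = row["class"]
    depth = sum(allele_counts.values())
    if cls.startswith("private-"):
        parent = cls.split("-", 1)[1]
        if depth == 0:
            return {parent: float("nan")}
        return {parent: allele_counts.get(row[parent], 0) / depth}
    if cls == "split-2-2":
        by_allele: dict[str, list[str]] = {}
        for p in PARENTS:
            by_allele.setdefault(row[p], []).append(p)
        out = {}
        for allele, pair in by_allele.items():
            key = "+".join(pair)
            out[key] = float("nan") if depth == 0 else allele_counts.get(allele, 0) / depth
        return out
    raise ValueError(f"sites of class {cls!r} carry no parent frequency information")
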