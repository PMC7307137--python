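"""Coverage-based genome diagnostics.

Depth is summarized in non-overlapping 10-kb windows per sample and used
for three screens: an aneuploidy check (chromosome mean depth normalized by
the genome median), the mitochondrial/nuclear depth-ratio time course (a
proxy for mtDNA copy number), and a clonal-expansion check on genome-wide
mean parental frequencies (a balanced pool sits at 0.25 per parent).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .frequency import FrequencyTrack, mean_parent_frequency


def window_depth(site_depths: pd.DataFrame, window: int = 10_000) -> pd.DataFrame:
    """Mean depth per non-overlapping window from per-site depths.

    `site_depths` needs columns chrom, pos (1-based), depth.  The trailing
    partial window is kept with its true span.
    """
    df = site_depths.copy()
    df["win"] = (df["pos"] - 1) // window
    rows = []
    for (chrom, w), sub in df.groupby(["chrom", "win"], sort=True):
        start = int(w) * window
        end = start + window
        rows.append((chrom, start, end, float(sub["depth"].mean()), len(sub)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth", "n_sites"])
    # clip trailing window ends to the last covered site
    for chrom, sub in out.groupby("chrom", sort=False):
        last = sub.index[-1]
        max_pos = int(site_depths.loc[site_depths["chrom"] == chrom, "pos"].max())
        if max_pos < out.at[last, "end"]:
            out.at[last, "end"] = max_pos
    return out


def aneuploidy_screen(depth_track: pd.DataFrame, low: float = 0.75,
                      high: float = 1.25, exclude: tuple[str, ...] = ("chrM",),
                      ) -> pd.DataFrame:
    """Flag chromosomes whose median-normalized mean depth leaves [low, high].

    In a pool a full single-chromosome gain shifts mean depth by the swept
    fraction, so the default band flags sweeps of a duplication above ~25%.
    """
    nuc = depth_track[~depth_track["chrom"].isin(exclude)]
    genome_median = float(nuc["mean_depth"].median())
    if genome_median == 0:
        raise ValueError("zero genome median depth")
    rows = []
    for chrom, sub in nuc.groupby("chrom", sort=False):
        norm = float(sub["mean_depth"].mean()) / genome_median
        rows.append((chrom, norm, not (low <= norm <= high)))
    return pd.DataFrame(rows, columns=["chrom", "normalized_depth", "flagged"])


@dataclass
class MitoRatioCourse:
    """Per-sample mito/nuclear depth ratios plus per-replica trend calls."""

    ratios: pd.DataFrame  # sample, condition, replicate, time, ratio
    trends: pd.DataFrame  # condition, replicate, monotone_decrease

    def decreasing_conditions(self) -> list[str]:
        """Conditions in which every replica decreases monotonically T0->T2."""
        agg = self.trends.groupby("condition")["monotone_decrease"].all()
        return sorted(agg.index[agg])


def mito_ratio(depth_track: pd.DataFrame, mito_chrom: str = "chrM") -> float:
    """mean mito depth / mean nuclear depth for one sample's DepthTrack."""
    is_mito = depth_track["chrom"] == mito_chrom
    if not is_mito.any():
        raise ValueError(f"mito contig {mito_chrom!r} absent from depth track")
    nuclear = float(depth_track.loc[~is_mito, "mean_depth"].mean())
    if nuclear == 0:
        raise ValueError("nuclear mean depth is zero; ratio undefined")
    return float(depth_track.loc[is_mito, "mean_depth"].mean()) / nuclear


def mito_ratio_course(depth_tracks: pd.DataFrame, mito_chrom: str = "chrM",
                      min_drop: float = 0.05) -> MitoRatioCourse:
    """Ratio per (condition, replicate, time) + monotone-decrease trend calls.

    `depth_tracks` is a long table with a `sample` column formatted
    ``{condition}_R{replicate}_{time}`` (the simulator's convention) plus
    chrom/start/end/mean_depth.  A replica is called monotonically
    decreasing only when each step loses more than `min_drop` of the ratio:
    with three time points a strict ordering arises by chance 1 time in 6,
    so noise-level ordering must not count, while Poisson depth noise stays
    below ~5% at 50x and genuine mitochondrial loss far exceeds it.
    """
    rows = []
    for sample, sub in depth_tracks.groupby("sample", sort=True):
        condition, rep, time = sample.rsplit("_", 2)
        rows.append((sample, condition, int(rep[1:]), time,
                     mito_ratio(sub, mito_chrom)))
    ratios = pd.DataFrame(rows, columns=["sample", "condition", "replicate",
                                         "time", "ratio"])
    trows = []
    for (condition, rep), sub in ratios.groupby(["condition", "replicate"]):
        sub = sub.set_index("time")["ratio"]
        course = [sub.get(t) for t in ("T0", "T1", "T2")]
        mono = (None not in course
                and course[1] < course[0] * (1 - min_drop)
                and course[2] < course[1] * (1 - min_drop))
        trows.append((condition, rep, bool(mono)))
    trends = pd.DataFrame(trows, columns=["condition", "replicate",
                                          "monotone_decrease"])
    return MitoRatioCourse(ratios=ratios, trends=trends)


def clonality_check(track: FrequencyTrack, sample_id: str,
                    tolerance: float = 0.10) -> dict:
    """No-clonal-expansion verdict from genome-wide mean parent frequencies.

    Passes when every parent's mean is within `tolerance` of the balanced
    expectation 0.25; otherwise names the offending parent.
    """
    means, diag = mean_parent_frequency(track, sample_id)
    dev = (means - 0.25).abs()
    worst = dev.idxmax()
    verdict = bool(dev.max() < tolerance)
    return {"pass": verdict, "means": means, "max_deviation": float(dev.max()),
            "offending_parent": None if verdict else worst,
            "max_parent": diag["max_parent"]}
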