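"""QTL mapping on windowed parental-frequency trajectories.

Two scans, each fitted against a treatment and a control condition:

* :class:`ZScoreScan` — allele-frequency changes Δx_ij(t) = x_ij(t) − x_ij(0)
  are standardized genome-wide per condition and time point,
  z = (Δx − μ)/σ, and z² averaged over replicates.  A window is a QTL when,
  for one parent, the replicate-mean z² exceeds the empirical quantile
  cut-off (99% strong / 95% weak) at both T1 and T2 in the treatment, the
  statistic increases from T1 to T2, and the same window does not pass the
  control condition's own cut-offs.

* :class:`AnovaScan` — one-way ANOVA on arcsin-√-transformed frequencies
  with time point as the factor, Benjamini–Hochberg adjusted; windows above
  the genome-wide 99% quantile of −log10(p_adj) in the treatment but not in
  the control are QTLs.

Significant windows merge (overlapping or book-ended) into intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import PARENTS, empirical_quantile
from .frequency import FrequencyTrack


@dataclass(frozen=True)
class QTLInterval:
    chrom: str
    start: int
    end: int
    method: str  # "zscore" | "anova"
    strength: str  # "strong" | "weak" | "anova-99q"
    score: float  # peak replicate-mean z² (T2) or peak -log10(p_adj)
    peak_start: int
    peak_end: int
    favored_parents: tuple[str, ...]
    direction: int = +1  # sign of Δx for the favored parent at the peak

    def as_bed_row(self) -> str:
        name = f"{self.method}:{self.strength}:{'|'.join(self.favored_parents)}"
        return f"{self.chrom}\t{self.start}\t{self.end}\t{name}\t{self.score:.4f}"


class DegenerateScanWarning(UserWarning):
    """Raised when σ of the standardization pool is zero."""


# --------------------------------------------------------------------------
# elementary operations


def delta_frequencies(track: FrequencyTrack, condition: str, time: str,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Δx_ij(t) = x_ij(t) − x_ij(T0) per replicate; (delta (W,4,R), mask (W,R)).

    Masked windows (in either the T0 or the time-t sample) propagate as
    masked.  Raises when the condition has no T0 samples.
    """
    f0, m0, reps0 = track.select(condition, "T0")
    ft, mt, repst = track.select(condition, time)
    if reps0 != repst:
        raise ValueError(f"replicate sets differ between T0 and {time}")
    mask = m0 | mt
    delta = ft - f0
    delta[np.repeat(mask[:, None, :], len(PARENTS), axis=1)] = np.nan
    return delta, mask


def zscore_standardize(delta: np.ndarray, mask: np.ndarray,
                       ) -> tuple[np.ndarray, float, float]:
    """Standardize a condition/time pool of Δx over all (window, parent,
    replicate) triples; returns (z, μ, σ) with population (ddof=0) σ.

    σ = 0 yields all-zero z and a :class:`DegenerateScanWarning`.
    """
    vals = delta[np.isfinite(delta)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite Δx values to standardize")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    if sigma == 0:
        warnings.warn("σ_Δx = 0: degenerate scan, all z set to 0",
                      DegenerateScanWarning, stacklevel=2)
        z = np.where(np.isfinite(delta), 0.0, np.nan)
        return z, mu, sigma
    return (delta - mu) / sigma, mu, sigma


def merge_windows(windows: pd.DataFrame) -> list[dict]:
    """Merge overlapping or book-ended windows into intervals.

    `windows` needs chrom/start/end columns; returns one dict per interval
    with the union span and the member row indices.
    """
    out: list[dict] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur = None
        for idx, row in sub.iterrows():
            if cur is not None and row["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], int(row["end"]))
                cur["members"].append(idx)
            else:
                if cur is not None:
                    out.append(cur)
                cur = {"chrom": chrom, "start": int(row["start"]),
                       "end": int(row["end"]), "members": [idx]}
        if cur is not None:
            out.append(cur)
    return out


def _overlaps(a: QTLInterval, chrom: str, start: int, end: int) -> bool:
    return a.chrom == chrom and a.start < end and start < a.end


# --------------------------------------------------------------------------
# z-score scan


@dataclass
class ScanResults:
    """Shared result surface: intervals + per-window statistics."""

    intervals: list[QTLInterval]
    window_stats: pd.DataFrame
    cutoffs: dict
    method: str = "scan"

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# driftmap {self.method} QTL intervals; 0-based half-open\n")
            for iv in self.intervals:
                fh.write(iv.as_bed_row() + "\n")

    def summary(self) -> str:
        lines = [f"{self.method} scan: {len(self.intervals)} QTL interval(s)"]
        for k, v in sorted(self.cutoffs.items()):
            lines.append(f"  cutoff {k}: {v:.4f}")
        for iv in self.intervals:
            lines.append(
                f"  {iv.chrom}:{iv.start}-{iv.end} [{iv.strength}] "
                f"score={iv.score:.3f} parent={'|'.join(iv.favored_parents)} "
                f"peak={iv.peak_start}-{iv.peak_end}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Genome-wide Manhattan-style plot of the per-window peak statistic."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        df = self.window_stats
        stat_col = "zsq_bar_T2" if "zsq_bar_T2" in df.columns else "neg_log10_padj"
        offset, ticks = 0, {}
        interval_spans = []
        for chrom, sub in df.groupby("chrom", sort=False):
            best = sub.groupby("start")[stat_col].max()
            ax.scatter(best.index.to_numpy() + offset + 5_000, best.to_numpy(), s=4)
            for iv in self.intervals:
                if iv.chrom == chrom:
                    interval_spans.append((iv.start + offset, iv.end + offset))
            ticks[chrom] = offset + sub["end"].max() / 2
            offset += sub["end"].max()
        ax.set_xticks(list(ticks.values()), list(ticks))
        ax.set_ylabel(stat_col)
        for lo, hi in interval_spans:
            ax.axvspan(lo, hi, alpha=0.2, color="red")
        return ax


class ZScoreScan:
    """z-score-square QTL scan over a treatment/control frequency track."""

    def __init__(self, track: FrequencyTrack, treatment: str = "SM60",
                 control: str = "SM300", strong_q: float = 0.99,
                 weak_q: float = 0.95, replicate_rule: str = "all"):
        if replicate_rule not in ("all", "mean"):
            raise ValueError("replicate_rule must be 'all' or 'mean'")
        self.track = track
        self.treatment = treatment
        self.control = control
        self.strong_q = strong_q
        self.weak_q = weak_q
        #: "all"  — every replicate's z² must clear the cut-off (the scan is
        #:          run in each population; a region counts only when it
        #:          passes in all of them);
        #: "mean" — the replicate-mean z̄² must clear the cut-off.
        self.replicate_rule = replicate_rule

    def _condition_stats(self, condition: str):
        """Per time point: Δx, z and the replicate-mean z² matrix (W, 4)."""
        out = {}
        for time in ("T1", "T2"):
            delta, mask = delta_frequencies(self.track, condition, time)
            z, mu, sigma = zscore_standardize(delta, mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                zsq = z ** 2
                zsq_bar = np.nanmean(zsq, axis=2)  # mean over replicates
                dmean = np.nanmean(delta, axis=2)
            out[time] = {"delta_mean": dmean, "z": z, "zsq": zsq,
                         "zsq_bar": zsq_bar, "mu": mu, "sigma": sigma}
        return out

    def fit(self) -> ScanResults:
        treat = self._condition_stats(self.treatment)
        ctrl = self._condition_stats(self.control)
        # cut-offs are quantiles of the statistic the rule tests: per-replicate
        # z² when every replicate must pass, replicate-mean z̄² otherwise
        stat_key = "zsq" if self.replicate_rule == "all" else "zsq_bar"
        cutoffs = {}
        for label, st in (("treatment", treat), ("control", ctrl)):
            for time in ("T1", "T2"):
                vals = st[time][stat_key]
                for q in (self.strong_q, self.weak_q):
                    cutoffs[(label, time, q)] = empirical_quantile(vals, q)

        def _clears(st: dict, label: str, time: str, q: float) -> np.ndarray:
            """(W, 4) bool: parent clears the cut-off at this time point."""
            cut = cutoffs[(label, time, q)]
            if self.replicate_rule == "all":
                zsq = st[time]["zsq"]  # (W, 4, R); NaN compares False
                with np.errstate(invalid="ignore"):
                    return (zsq > cut).all(axis=2) & np.isfinite(zsq).all(axis=2)
            with np.errstate(invalid="ignore"):
                return np.nan_to_num(
                    (st[time]["zsq_bar"] > cut).astype(float)).astype(bool)

        def _passing(q: float) -> tuple[np.ndarray, np.ndarray]:
            t1b, t2b = treat["T1"]["zsq_bar"], treat["T2"]["zsq_bar"]
            with np.errstate(invalid="ignore"):
                increase = np.nan_to_num((t2b > t1b).astype(float)).astype(bool)
            hit = (_clears(treat, "treatment", "T1", q)
                   & _clears(treat, "treatment", "T2", q) & increase)
            chit = (_clears(ctrl, "control", "T1", q)
                    & _clears(ctrl, "control", "T2", q))
            return hit.any(axis=1) & ~chit.any(axis=1), hit

        strong_w, strong_pj = _passing(self.strong_q)
        weak_w, weak_pj = _passing(self.weak_q)
        weak_only = weak_w & ~strong_w

        intervals = []
        for strength, wsel, pj in (("strong", strong_w, strong_pj),
                                   ("weak", weak_only, weak_pj)):
            sub = self.track.windows[wsel]
            for merged in merge_windows(sub):
                iv = self._interval_from(merged, treat, pj, strength)
                if strength == "weak" and any(
                        _overlaps(s, iv.chrom, iv.start, iv.end)
                        for s in intervals if s.strength == "strong"):
                    continue
                intervals.append(iv)

        stats_df = self._window_frame(treat, ctrl)
        return ScanResults(intervals=intervals, window_stats=stats_df,
                           cutoffs=cutoffs, method="zscore")

    def _interval_from(self, merged: dict, treat: dict, passing_pj: np.ndarray,
                       strength: str) -> QTLInterval:
        zsq2 = treat["T2"]["zsq_bar"]
        members = merged["members"]
        peak = max(members, key=lambda w: np.nanmax(zsq2[w]))
        pj = passing_pj[peak]
        row_max = np.nanmax(np.where(pj, zsq2[peak], -np.inf))
        if not np.isfinite(row_max):  # no parent passed at the peak window
            row_max = np.nanmax(zsq2[peak])
            fav = tuple(p for j, p in enumerate(PARENTS)
                        if zsq2[peak, j] == row_max)
        else:
            fav = tuple(p for j, p in enumerate(PARENTS)
                        if pj[j] and zsq2[peak, j] == row_max)
        j0 = PARENTS.index(fav[0])
        direction = int(np.sign(treat["T2"]["delta_mean"][peak, j0]) or 1)
        wrow = self.track.windows.loc[peak]
        return QTLInterval(chrom=merged["chrom"], start=merged["start"],
                           end=merged["end"], method="zscore", strength=strength,
                           score=float(row_max), peak_start=int(wrow["start"]),
                           peak_end=int(wrow["end"]), favored_parents=fav,
                           direction=direction)

    def _window_frame(self, treat: dict, ctrl: dict) -> pd.DataFrame:
        wins = self.track.windows
        recs = []
        for j, parent in enumerate(PARENTS):
            for w in range(len(wins)):
                recs.append((wins.at[w, "chrom"], wins.at[w, "start"],
                             wins.at[w, "end"], parent,
                             treat["T1"]["zsq_bar"][w, j], treat["T2"]["zsq_bar"][w, j],
                             ctrl["T1"]["zsq_bar"][w, j], ctrl["T2"]["zsq_bar"][w, j],
                             treat["T2"]["delta_mean"][w, j]))
        return pd.DataFrame(recs, columns=["chrom", "start", "end", "parent",
                                           "zsq_bar_T1", "zsq_bar_T2",
                                           "ctrl_zsq_bar_T1", "ctrl_zsq_bar_T2",
                                           "delta_mean_T2"])


# --------------------------------------------------------------------------
# ANOVA scan


def anova_time_factor(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way F test with time as the factor.

    `y` has shape (..., R, T): replicates within T time-point groups.
    Entirely constant cells give F = 0, p = 1 (no evidence, not an error).
    """
    groups = [y[..., t] for t in range(y.shape[-1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*[np.moveaxis(g, -1, 0) for g in groups], axis=0)
        f = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    flat = np.stack(groups, axis=-1)
    const = np.nanstd(flat, axis=(-1, -2)) == 0
    f = np.where(const, 0.0, f)
    p = np.where(const, 1.0, p)
    return f, p


class AnovaScan:
    """arcsin-√ ANOVA QTL scan with BH-adjusted time-factor p-values."""

    def __init__(self, track: FrequencyTrack, treatment: str = "SM60",
                 control: str = "SM300", cutoff_q: float = 0.99,
                 adjust: str = "fdr_bh"):
        self.track = track
        self.treatment = treatment
        self.control = control
        self.cutoff_q = cutoff_q
        self.adjust = adjust

    def _condition_scores(self, condition: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(F, p_adj, −log10 p_adj) per (window, parent); NaN where masked."""
        from statsmodels.stats.multitest import multipletests

        cubes, masks = [], []
        reps_ref = None
        for time in ("T0", "T1", "T2"):
            f, m, reps = self.track.select(condition, time)
            if reps_ref is None:
                reps_ref = reps
            elif reps != reps_ref:
                raise ValueError("replicate sets differ across time points")
            cubes.append(f)
            masks.append(m)
        if len(reps_ref) < 2:
            raise ValueError("ANOVA scan needs >= 2 replicates per time point")
        y = np.stack(cubes, axis=-1)  # (W, 4, R, T)
        y = np.arcsin(np.sqrt(np.clip(y, 0.0, 1.0)))
        valid = ~np.stack(masks, axis=-1).any(axis=(1, 2))  # (W,)
        f_stat = np.full(y.shape[:2], np.nan)
        p_adj = np.full(y.shape[:2], np.nan)
        if valid.any():
            f_v, p_v = anova_time_factor(y[valid])
            rej, padj_flat, *_ = multipletests(p_v.ravel(), method=self.adjust)
            f_stat[valid] = f_v
            p_adj[valid] = padj_flat.reshape(p_v.shape)
        with np.errstate(divide="ignore"):
            score = -np.log10(np.clip(p_adj, 1e-300, None))
        return f_stat, p_adj, score

    def fit(self) -> ScanResults:
        f_t, padj_t, score_t = self._condition_scores(self.treatment)
        f_c, padj_c, score_c = self._condition_scores(self.control)
        cutoffs = {"treatment": empirical_quantile(score_t, self.cutoff_q),
                   "control": empirical_quantile(score_c, self.cutoff_q)}
        with np.errstate(invalid="ignore"):
            hit = np.nan_to_num((score_t > cutoffs["treatment"]).astype(float)).astype(bool)
            chit = np.nan_to_num((score_c > cutoffs["control"]).astype(float)).astype(bool)
        wsel = hit.any(axis=1) & ~chit.any(axis=1)

        intervals = []
        for merged in merge_windows(self.track.windows[wsel]):
            members = merged["members"]
            peak = max(members, key=lambda w: np.nanmax(score_t[w]))
            best = np.nanmax(np.where(hit[peak], score_t[peak], -np.inf))
            fav = tuple(p for j, p in enumerate(PARENTS)
                        if hit[peak, j] and score_t[peak, j] == best)
            wrow = self.track.windows.loc[peak]
            intervals.append(QTLInterval(
                chrom=merged["chrom"], start=merged["start"], end=merged["end"],
                method="anova", strength=f"anova-{int(self.cutoff_q * 100)}q",
                score=float(best), peak_start=int(wrow["start"]),
                peak_end=int(wrow["end"]), favored_parents=fav))

        wins = self.track.windows
        recs = []
        for j, parent in enumerate(PARENTS):
            for w in range(len(wins)):
                recs.append((wins.at[w, "chrom"], wins.at[w, "start"],
                             wins.at[w, "end"], parent, f_t[w, j], padj_t[w, j],
                             score_t[w, j], score_c[w, j]))
        stats_df = pd.DataFrame(recs, columns=["chrom", "start", "end", "parent",
                                               "F", "p_adj", "neg_log10_padj",
                                               "ctrl_neg_log10_padj"])
        return ScanResults(intervals=intervals, window_stats=stats_df,
                           cutoffs=cutoffs, method="anova")
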