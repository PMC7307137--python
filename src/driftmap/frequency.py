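"""Windowed parental allele-frequency estimation from pooled site counts.

Only private-allele sites (one founder carries a distinct allele) identify a
single parent, so the per-window estimate of parent j's frequency is the
depth-weighted mean of ``private-allele reads / depth`` over the private-j
sites in the window; the four per-parent estimates are then renormalized to
sum to one.  Windows default to 10 kb spans every 2 kb, half-open [start,
start+10000) with 0-based starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import PARENTS, window_starts
from .markers import classify_markers
from .simulate import SampleCounts


@dataclass
class FrequencyTrack:
    """Parental frequencies x_ij per window i, parent j and sample.

    `freq` has shape (windows, 4 parents, samples) with NaN at masked
    entries; `mask` (windows, samples) is True where a window lacks marker
    support for some parent in that sample.
    """

    windows: pd.DataFrame  # chrom, start, end  (0-based half-open)
    samples: pd.DataFrame  # sample_id, replicate, condition, time
    freq: np.ndarray
    n_markers: np.ndarray  # (windows, 4, samples): informative sites used
    mask: np.ndarray  # (windows, samples)

    parents: tuple[str, ...] = PARENTS

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def sample_index(self, sample_id: str) -> int:
        hits = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(hits) != 1:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(hits[0])

    def select(self, condition: str, time: str) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """(freq (W,4,R), mask (W,R), replicate labels) for one condition/time,
        ordered by replicate."""
        sub = self.samples[(self.samples["condition"] == condition)
                           & (self.samples["time"] == time)].sort_values("replicate")
        if sub.empty:
            raise KeyError(f"no samples for ({condition}, {time})")
        idx = sub.index.to_numpy()
        return self.freq[:, :, idx], self.mask[:, idx], sub["replicate"].tolist()

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for s, srow in self.samples.iterrows():
            for w, wrow in self.windows.iterrows():
                for j, parent in enumerate(self.parents):
                    recs.append((wrow["chrom"], wrow["start"], wrow["end"], parent,
                                 srow["sample_id"], srow["replicate"], srow["condition"],
                                 srow["time"], self.freq[w, j, s],
                                 int(self.n_markers[w, j, s])))
        return pd.DataFrame(recs, columns=["chrom", "start", "end", "parent",
                                           "sample_id", "replicate", "condition",
                                           "time", "freq", "n_markers"])

    def write_tsv(self, path, header_extra: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# driftmap frequency track; coords 0-based half-open\n")
            for k, v in (header_extra or {}).items():
                fh.write(f"# {k}={v}\n")
            # "NA" is a founder label; missing values are written as "nan"
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="nan")

    @classmethod
    def read_tsv(cls, path) -> "FrequencyTrack":
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                         na_values=["nan", ""])
        windows = (df[["chrom", "start", "end"]].drop_duplicates()
                   .reset_index(drop=True))
        samples = (df[["sample_id", "replicate", "condition", "time"]]
                   .drop_duplicates().reset_index(drop=True))
        wkey = {t: i for i, t in enumerate(map(tuple, windows.to_numpy()))}
        skey = {t: i for i, t in enumerate(samples["sample_id"])}
        pkey = {p: j for j, p in enumerate(PARENTS)}
        freq = np.full((len(windows), 4, len(samples)), np.nan)
        nmk = np.zeros((len(windows), 4, len(samples)), dtype=np.int64)
        for rec in df.itertuples(index=False):
            w = wkey[(rec.chrom, rec.start, rec.end)]
            s = skey[rec.sample_id]
            j = pkey[rec.parent]
            freq[w, j, s] = rec.freq
            nmk[w, j, s] = rec.n_markers
        mask = np.isnan(freq).any(axis=1)
        return cls(windows=windows, samples=samples, freq=freq, n_markers=nmk, mask=mask)


def _window_table(marker_table: pd.DataFrame, chrom_lengths: dict[str, int] | None,
                  window: int, step: int) -> pd.DataFrame:
    rows = []
    for chrom in marker_table["chrom"].unique():
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(marker_table.loc[marker_table["chrom"] == chrom, "pos"].max())
        for start in window_starts(length, window, step):
            rows.append((chrom, int(start), int(min(start + window, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_frequencies(samples: list[SampleCounts], marker_table: pd.DataFrame,
                       window: int = 10_000, step: int = 2_000,
                       min_markers: int = 1,
                       chrom_lengths: dict[str, int] | None = None,
                       ) -> FrequencyTrack:
    """Estimate x_ij(t) per sliding window from site-level allele counts.

    A window is masked for a sample when any parent has fewer than
    `min_markers` private sites with non-zero depth inside it; unmasked
    windows are renormalized to sum to 1 across parents.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if "class" not in marker_table.columns:
        marker_table = classify_markers(marker_table)
    wins = _window_table(marker_table, chrom_lengths, window, step)

    is_priv = marker_table["class"].str.startswith("private-")
    priv = marker_table[is_priv].copy()
    priv["parent"] = priv["class"].str.split("-").str[1]
    priv["parent_idx"] = priv["parent"].map({p: j for j, p in enumerate(PARENTS)})
    priv["allele"] = [row[row["class"].split("-")[1]] for _, row in priv.iterrows()]

    # site -> containing windows (a site can sit in up to window/step windows)
    exp_site, exp_win = [], []
    priv = priv.reset_index(drop=True)
    for chrom, wsub in wins.groupby("chrom", sort=False):
        starts = wsub["start"].to_numpy()
        base = wsub.index.to_numpy()
        psub = priv[priv["chrom"] == chrom]
        p0 = psub["pos"].to_numpy() - 1  # 1-based -> 0-based
        lo = np.searchsorted(starts, p0 - window, side="right")
        hi = np.searchsorted(starts, p0, side="right")
        for site, l, h in zip(psub.index.to_numpy(), lo, hi):
            exp_site.extend([site] * (h - l))
            exp_win.extend(base[l:h])
    exp_site = np.asarray(exp_site, dtype=np.int64)
    exp_win = np.asarray(exp_win, dtype=np.int64)

    n_w, n_s = len(wins), len(samples)
    freq = np.full((n_w, 4, n_s), np.nan)
    nmk = np.zeros((n_w, 4, n_s), dtype=np.int64)
    mask = np.zeros((n_w, n_s), dtype=bool)
    site_key = pd.MultiIndex.from_frame(priv[["chrom", "pos"]])
    allele_key = pd.MultiIndex.from_frame(priv[["chrom", "pos", "allele"]])
    parent_of_site = priv["parent_idx"].to_numpy()

    meta = []
    for s, sc in enumerate(samples):
        meta.append((sc.sample_id, sc.replicate, sc.condition, sc.time))
        depth = (sc.counts.groupby(["chrom", "pos"], sort=False)["count"].sum()
                 .reindex(site_key).fillna(0).to_numpy())
        pcount = (sc.counts.set_index(["chrom", "pos", "allele"])["count"]
                  .reindex(allele_key).fillna(0).to_numpy())
        valid = depth > 0
        x = np.where(valid, pcount / np.where(valid, depth, 1), np.nan)

        wsum = np.zeros((n_w, 4))
        wtot = np.zeros((n_w, 4))
        nval = np.zeros((n_w, 4), dtype=np.int64)
        ok = valid[exp_site]
        es, ew = exp_site[ok], exp_win[ok]
        pj = parent_of_site[es]
        np.add.at(wsum, (ew, pj), depth[es] * x[es])
        np.add.at(wtot, (ew, pj), depth[es])
        np.add.at(nval, (ew, pj), 1)

        est = np.where(wtot > 0, wsum / np.where(wtot > 0, wtot, 1), np.nan)
        bad = (nval < min_markers).any(axis=1)
        tot = np.nansum(np.where(nval >= min_markers, est, np.nan), axis=1)
        bad |= ~(tot > 0)
        good = ~bad
        freq[good, :, s] = est[good] / tot[good, None]
        nmk[:, :, s] = nval
        mask[:, s] = bad
    sdf = pd.DataFrame(meta, columns=["sample_id", "replicate", "condition", "time"])
    return FrequencyTrack(windows=wins, samples=sdf, freq=freq, n_markers=nmk, mask=mask)


def mean_parent_frequency(track: FrequencyTrack, sample_id: str,
                          ) -> tuple[pd.Series, dict]:
    """Genome-wide unweighted mean frequency per parent for one sample.

    Also reports the largest single-parent mean as a clonal-expansion
    diagnostic.  Raises when every window is masked.
    """
    s = track.sample_index(sample_id)
    live = ~track.mask[:, s]
    if not live.any():
        raise ValueError(f"all windows masked for sample {sample_id!r}")
    means = pd.Series(track.freq[live, :, s].mean(axis=0), index=list(track.parents))
    diag = {"max_parent": means.idxmax(), "max_mean": float(means.max())}
    return means, diag
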