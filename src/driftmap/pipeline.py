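"""End-to-end orchestration: simulate -> estimate -> map -> report.

Stages communicate through plain-text files so partial pipelines are
runnable in isolation; every output carries the config hash and seed, and
re-running with the same config reproduces outputs bit-for-bit (analysis
stages are deterministic; all randomness lives in the simulator).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from ._util import TIMES
from .coverage import aneuploidy_screen, clonality_check, mito_ratio_course
from .expression import (ase_quantile_flags, assign_parent_of_origin,
                         chisq_uniform, consistency_across_replicas,
                         origin_distribution, select_de_genes)
from .frequency import window_frequencies
from .growth import fit_plate
from .qtl import AnovaScan, ZScoreScan
from .simulate import simulate_experiment


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    outdir: str = "driftmap_run"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    window: int = 10_000
    step: int = 2_000
    min_markers: int = 1
    strong_q: float = 0.99
    weak_q: float = 0.95
    anova_q: float = 0.99
    adjust: str = "fdr_bh"
    treatment: str = "SM60"
    control: str = "SM300"
    mito_chrom: str = "chrM"
    recovery_slop: int = 20_000  # bp slack when matching intervals to truth
    inputs: dict = field(default_factory=dict)  # paths when simulate=False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def validate_inputs(paths: dict) -> dict:
    """Schema/completeness checks on the input file set.

    Returns {"ok": bool, "failures": [str, ...]}; never partially runs.
    """
    failures: list[str] = []
    for key, p in paths.items():
        if not Path(p).exists():
            failures.append(f"missing input file: {key} -> {p}")
    if failures:
        return {"ok": False, "failures": failures}
    if "markers" in paths:
        mk = dio.read_marker_table(paths["markers"])
        need = {"chrom", "pos", "NA", "SA", "WA", "WE"}
        if not need.issubset(mk.columns):
            failures.append(f"marker table missing columns {need - set(mk.columns)}")
    if "counts" in paths:
        counts = dio.read_counts(paths["counts"])
        seen = {(c.condition, c.replicate, c.time) for c in counts}
        for cond in {c.condition for c in counts}:
            for rep in {c.replicate for c in counts if c.condition == cond}:
                for t in TIMES:
                    if (cond, rep, t) not in seen:
                        failures.append(f"missing sample {cond}_R{rep}_{t}")
        for c in counts:
            if (c.counts["count"] < 0).any():
                failures.append(f"negative counts in {c.sample_id}")
    if "depth" in paths:
        d = dio.read_depth(paths["depth"])
        if not {"sample", "chrom", "start", "end", "mean_depth"}.issubset(d.columns):
            failures.append("depth table missing required columns")
    return {"ok": not failures, "failures": failures}


def _interval_hits(intervals, qtls, slop: int) -> list[dict]:
    hits = []
    for q in qtls:
        matched = [iv for iv in intervals
                   if iv.chrom == q.chrom
                   and iv.start - slop <= q.pos <= iv.end + slop]
        hits.append({"chrom": q.chrom, "pos": q.pos, "parent": q.favored_parent,
                     "s": q.s, "recovered": bool(matched),
                     "matched": [[iv.chrom, iv.start, iv.end, iv.strength,
                                  list(iv.favored_parents)] for iv in matched]})
    return hits


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full workflow; returns the report dict (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    if config.simulate:
        sim_conf = dio.config_from_dict({**config.sim, "seed": config.seed})
        bundle = simulate_experiment(sim_conf)
        paths = dio.write_bundle(bundle, outdir / "inputs")
        report["config_hash"] = dio.config_hash(sim_conf)
        marker_table = bundle.founders.table
        counts = bundle.counts
        depth = bundle.depth
        de_table, parent_counts = bundle.de_table, bundle.parent_counts
        ase_freqs, growth = bundle.ase_freqs, bundle.growth
        truth = bundle.truth
        chrom_lengths = bundle.founders.chrom_lengths
        treatment, control = sim_conf.treatment, sim_conf.control
    else:
        check = validate_inputs(config.inputs)
        if not check["ok"]:
            raise ValueError("input validation failed: " + "; ".join(check["failures"]))
        paths = {k: Path(v) for k, v in config.inputs.items()}
        marker_table = dio.read_marker_table(paths["markers"])
        counts = dio.read_counts(paths["counts"])
        depth = dio.read_depth(paths["depth"]) if "depth" in paths else None
        de_table = dio.read_de_table(paths["de_table"]) if "de_table" in paths else None
        parent_counts = (dio.read_parent_counts(paths["parent_counts"])
                         if "parent_counts" in paths else None)
        ase_freqs = dio.read_ase_freqs(paths["ase_freqs"]) if "ase_freqs" in paths else None
        growth = dio.read_growth(paths["growth"]) if "growth" in paths else None
        truth = None
        chrom_lengths = None
        treatment, control = config.treatment, config.control

    header = {"seed": config.seed, "config_hash": report.get("config_hash", "external")}

    # frequency estimation
    track = window_frequencies(counts, marker_table, window=config.window,
                               step=config.step, min_markers=config.min_markers,
                               chrom_lengths=chrom_lengths)
    track.write_tsv(outdir / "frequency_track.tsv", header)

    # QTL scans
    zres = ZScoreScan(track, treatment=treatment, control=control,
                      strong_q=config.strong_q, weak_q=config.weak_q).fit()
    ares = AnovaScan(track, treatment=treatment, control=control,
                     cutoff_q=config.anova_q, adjust=config.adjust).fit()
    zres.to_bed(outdir / "qtl_zscore.bed")
    ares.to_bed(outdir / "qtl_anova.bed")
    dio._write_tsv(zres.window_stats, outdir / "zscore_windows.tsv", header)
    dio._write_tsv(ares.window_stats, outdir / "anova_windows.tsv", header)
    report["n_qtl_zscore"] = len(zres.intervals)
    report["n_qtl_anova"] = len(ares.intervals)

    # coverage diagnostics
    if depth is not None:
        per_sample = []
        for sample, sub in depth.groupby("sample", sort=True):
            scr = aneuploidy_screen(sub, exclude=(config.mito_chrom,))
            scr.insert(0, "sample", sample)
            per_sample.append(scr)
        aneu = pd.concat(per_sample, ignore_index=True)
        dio._write_tsv(aneu, outdir / "aneuploidy.tsv", header)
        report["n_aneuploidy_flags"] = int(aneu["flagged"].sum())
        course = mito_ratio_course(depth, mito_chrom=config.mito_chrom)
        dio._write_tsv(course.ratios, outdir / "mito_ratio.tsv", header)
        report["mito_decreasing_conditions"] = course.decreasing_conditions()

    # clonality at T0 (first treatment replicate)
    t0_sample = f"{treatment}_R1_T0"
    try:
        clon = clonality_check(track, t0_sample)
        report["clonality"] = {"pass": clon["pass"],
                               "means": {k: round(float(v), 4)
                                         for k, v in clon["means"].items()}}
    except (KeyError, ValueError):
        report["clonality"] = None

    # expression analyses
    if de_table is not None and parent_counts is not None:
        up, down = select_de_genes(de_table, 2.0, 2.0)
        up3, down3 = select_de_genes(de_table, 3.0, 2.0)
        report["de_counts"] = {"up_2": len(up), "down_2": len(down),
                               "up_3": len(up3), "down_3": len(down3)}
        expr_report = {}
        for label, genes in (("up", up3["gene"]), ("down", down3["gene"])):
            assign = assign_parent_of_origin(parent_counts, genes)
            dist = origin_distribution(assign)
            stat, dfree, p = chisq_uniform(dist)
            # both denominators: all selected genes vs assignable genes only
            expr_report[label] = {"distribution": dist.to_dict(),
                                  "n_genes": int(len(genes)),
                                  "n_assigned": int(dist.sum()),
                                  "chisq": stat, "df": dfree, "p": p}
        report["parent_of_origin"] = expr_report
        if ase_freqs is not None:
            flags = [ase_quantile_flags(sub)
                     for _, sub in ase_freqs.groupby("replicate", sort=True)]
            consistent = consistency_across_replicas(flags)
            dio._write_tsv(consistent, outdir / "ase_consistent.tsv", header)
            report["n_consistent_ase"] = len(consistent)

    # growth curves
    if growth is not None:
        fits = fit_plate(growth)
        dio._write_tsv(fits, outdir / "growth_fits.tsv", header)
        report["growth_params_mean"] = {c: round(float(fits[c].mean()), 4)
                                        for c in ("lag", "rate", "efficiency")}

    # recovery summary against planted truth
    if truth is not None and truth.qtls:
        report["recovery"] = {
            "zscore": _interval_hits(zres.intervals, truth.qtls, config.recovery_slop),
            "anova": _interval_hits(ares.intervals, truth.qtls, config.recovery_slop),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    report["paths"] = {k: str(v) for k, v in paths.items()}
    return report


__all__ = ["RunConfig", "run_end_to_end", "validate_inputs"]
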