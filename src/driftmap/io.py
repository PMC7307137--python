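"""Plain-text I/O for every pipeline artifact.

All TSVs carry ``# key=value`` comment headers stating the coordinate
convention (marker/count positions are 1-based; window/BED coordinates are
0-based half-open) plus the config hash and seed when written by the
pipeline, so any output can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from ._util import PARENTS
from .simulate import SampleCounts, SimConfig, QTL


# "NA" is a founder label here, never a missing value: missing cells are
# written as "nan" and pandas' default NA tokens are disabled on read.
def _write_tsv(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="nan")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                       na_values=["nan", ""])


def read_header(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("# ").rstrip("\n").split("=", 1)
                out[k] = v
    return out


def config_hash(config) -> str:
    """Short stable hash of a config dataclass (provenance stamping)."""
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def config_to_dict(config: SimConfig) -> dict:
    d = dict(config.__dict__)
    d["qtls"] = [[q.chrom, q.pos, q.favored_parent, q.s] for q in config.qtls]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["qtls"] = [QTL(chrom=q[0], pos=int(q[1]), favored_parent=q[2], s=float(q[3]))
                 for q in d.get("qtls", [])]
    return SimConfig(**d)


# --------------------------------------------------------------------------
# per-artifact readers/writers


def write_marker_table(table: pd.DataFrame, path, header: dict | None = None) -> None:
    h = {"format": "driftmap marker table", "coords": "1-based", **(header or {})}
    _write_tsv(table, path, h)


def read_marker_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_counts(samples: list[SampleCounts], path, header: dict | None = None) -> None:
    frames = []
    for sc in samples:
        df = sc.counts.copy()
        df.insert(0, "sample", sc.sample_id)
        frames.append(df)
    h = {"format": "driftmap site allele counts", "coords": "1-based", **(header or {})}
    _write_tsv(pd.concat(frames, ignore_index=True), path, h)


def read_counts(path) -> list[SampleCounts]:
    df = _read_tsv(path)
    out = []
    for sample, sub in df.groupby("sample", sort=True):
        condition, rep, time = sample.rsplit("_", 2)
        out.append(SampleCounts(replicate=int(rep[1:]), condition=condition,
                                time=time,
                                counts=sub.drop(columns="sample").reset_index(drop=True)))
    return out


def write_depth(depth: pd.DataFrame, path, header: dict | None = None) -> None:
    h = {"format": "driftmap window depth", "coords": "0-based half-open",
         **(header or {})}
    _write_tsv(depth, path, h)


read_depth = _read_tsv


def write_de_table(de: pd.DataFrame, path, header: dict | None = None) -> None:
    _write_tsv(de, path, {"format": "DE results", **(header or {})})


read_de_table = _read_tsv
read_parent_counts = _read_tsv
read_ase_freqs = _read_tsv
read_growth = _read_tsv


def write_truth(truth, config: SimConfig, path) -> None:
    """Planted truth as JSON (frequencies omitted: they are arrays; the
    QTLs, generations, DE truth and mito ratios are what recovery needs)."""
    payload = {
        "qtls": [[q.chrom, q.pos, q.favored_parent, q.s] for q in truth.qtls],
        "generations": truth.generations,
        "mito_ratio": {f"{c}:{t}": r for (c, t), r in truth.mito_ratio.items()},
        "ase_outliers": truth.ase_outliers,
        "growth_params": truth.growth_params,
        "de_genes": (truth.de_genes.to_dict("records")
                     if truth.de_genes is not None else None),
        "config": config_to_dict(config),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_founder_vcf(marker_table: pd.DataFrame, path) -> None:
    """Founder genotypes at every marker as a VCF v4.2 with 4 sample columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=driftmap-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tFORMAT\t"
                 + "\t".join(PARENTS) + "\n")
        for rec in marker_table.to_dict("records"):
            alleles = []
            for p in PARENTS:
                if rec[p] not in alleles:
                    alleles.append(rec[p])
            ref, alts = alleles[0], alleles[1:]
            gts = "\t".join(str(alleles.index(rec[p])) for p in PARENTS)
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t.\t{ref}\t{','.join(alts)}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_inputs(path) -> tuple[pd.DataFrame, list]:
    """Marker table + pooled counts from one VCF v4.2.

    The VCF must carry genotype columns named NA, SA, WA, WE (haploid GT
    giving each founder's allele) plus one column per pooled sample named
    ``{condition}_R{replicate}_{time}`` with an AD field (allelic depths in
    REF,ALT order).  Returns (marker_table, [SampleCounts, ...]).
    """
    import pysam

    from .simulate import SampleCounts

    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        founders = [s for s in sample_names if s in PARENTS]
        pools = [s for s in sample_names if s not in PARENTS]
        if sorted(founders) != sorted(PARENTS):
            raise ValueError(f"VCF needs genotype columns for {PARENTS}, "
                             f"found {founders}")
        mrows = []
        crows: dict[str, list] = {s: [] for s in pools}
        for rec in vf:
            alleles = (rec.ref, *(rec.alts or ()))
            row = {"chrom": rec.chrom, "pos": rec.pos}
            for p in PARENTS:
                gt = rec.samples[p]["GT"][0]
                if gt is None:
                    break
                row[p] = alleles[gt]
            else:
                mrows.append(row)
                for s in pools:
                    ad = rec.samples[s].get("AD")
                    if ad is None:
                        ad = [0] * len(alleles)
                    for allele, depth in zip(alleles, ad):
                        crows[s].append((rec.chrom, rec.pos, allele,
                                         int(depth or 0)))
    table = pd.DataFrame(mrows)
    samples = []
    for s in pools:
        condition, rep, time = s.rsplit("_", 2)
        samples.append(SampleCounts(
            replicate=int(rep[1:]), condition=condition, time=time,
            counts=pd.DataFrame(crows[s],
                                columns=["chrom", "pos", "allele", "count"])))
    return table, samples


def write_bundle(bundle, outdir, extra_header: dict | None = None) -> dict[str, Path]:
    """Write every artifact of a simulated experiment; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = {"config_hash": config_hash(bundle.config), "seed": bundle.config.seed,
         **(extra_header or {})}
    paths = {
        "markers": outdir / "markers.tsv",
        "counts": outdir / "counts.tsv",
        "depth": outdir / "depth.tsv",
        "de_table": outdir / "de_table.tsv",
        "parent_counts": outdir / "parent_counts.tsv",
        "ase_freqs": outdir / "ase_freqs.tsv",
        "growth": outdir / "growth.tsv",
        "truth": outdir / "truth.json",
        "founders_vcf": outdir / "founders.vcf",
    }
    write_marker_table(bundle.founders.table, paths["markers"], h)
    write_counts(bundle.counts, paths["counts"], h)
    write_depth(bundle.depth, paths["depth"], h)
    write_de_table(bundle.de_table, paths["de_table"], h)
    _write_tsv(bundle.parent_counts, paths["parent_counts"], h)
    _write_tsv(bundle.ase_freqs, paths["ase_freqs"], h)
    _write_tsv(bundle.growth, paths["growth"], h)
    write_truth(bundle.truth, bundle.config, paths["truth"])
    write_founder_vcf(bundle.founders.table, paths["founders_vcf"])
    return paths
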