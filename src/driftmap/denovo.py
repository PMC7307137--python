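"""De novo mutation calling by intersection filtering.

Variants are accepted as de novo only when (1) called by both of two
independent callers (matching on chrom, pos, ref, alt, filter-passing
calls only), (2) absent from the founder strains' pre-existing variation,
(3) strictly deeper than 10 total reads with strictly more than 6 reads
supporting the alternate allele, and (4) outside repeat-rich exclusion
regions such as chromosome ends.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    total_depth: int | None = None
    alt_depth: int | None = None
    caller: str = ""
    filter_status: str = "PASS"

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if (self.total_depth is not None and self.alt_depth is not None
                and self.alt_depth > self.total_depth):
            raise ValueError("alt depth exceeds total depth")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ExclusionRegions:
    """Sorted, merged repeat/subtelomeric intervals (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples) -> "ExclusionRegions":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[chrom] = out
        return cls(intervals=merged)

    @classmethod
    def from_bed(cls, path) -> "ExclusionRegions":
        tuples = []
        last = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, *_ = line.split("\t")
                start = int(start)
                if chrom in last and start < last[chrom]:
                    raise ValueError(f"exclusion BED not sorted at {chrom}:{start}")
                last[chrom] = start
                tuples.append((chrom, start, int(end)))
        return cls.from_tuples(tuples)

    @classmethod
    def chromosome_ends(cls, chrom_lengths: dict[str, int],
                        distance: int = 20_000) -> "ExclusionRegions":
        tuples = []
        for chrom, length in chrom_lengths.items():
            tuples.append((chrom, 0, min(distance, length)))
            tuples.append((chrom, max(0, length - distance), length))
        return cls.from_tuples(tuples)

    def contains(self, chrom: str, pos: int) -> bool:
        """Is 1-based position `pos` inside any interval?"""
        ivs = self.intervals.get(chrom, [])
        p0 = pos - 1
        i = bisect_right([s for s, _ in ivs], p0) - 1
        return i >= 0 and p0 < ivs[i][1]


# --------------------------------------------------------------------------
# filter steps (each a pure function; the chain composes them)


def intersect_callers(calls_a, calls_b, depth_from: str = "a") -> list[VariantCall]:
    """Variants called identically (chrom, pos, ref, alt) by both callers.

    Depth fields are taken from caller A by default (`depth_from="b"` flips).
    Only filter-passing calls should be supplied.
    """
    b_keys = {v.key for v in calls_b}
    if depth_from == "a":
        return [v for v in calls_a if v.key in b_keys]
    a_keys = {v.key for v in calls_a}
    return [v for v in calls_b if v.key in a_keys]


def subtract_founders(calls, founder_variants, allele_aware: bool = True,
                      ) -> list[VariantCall]:
    """Drop calls present in the founders' pre-existing variation.

    Allele-aware by default: a call at a founder position with a different
    alt allele is kept.  `allele_aware=False` subtracts on position only.
    """
    if allele_aware:
        founder_keys = {v.key for v in founder_variants}
        return [v for v in calls if v.key not in founder_keys]
    founder_pos = {(v.chrom, v.pos) for v in founder_variants}
    return [v for v in calls if (v.chrom, v.pos) not in founder_pos]


def depth_filter(calls, min_total: int = 10, min_alt: int = 6,
                 dropped: list | None = None) -> list[VariantCall]:
    """Keep calls with total depth strictly > min_total and alt depth
    strictly > min_alt; calls missing depth fields are dropped (logged)."""
    out = []
    for v in calls:
        if v.total_depth is None or v.alt_depth is None:
            if dropped is not None:
                dropped.append((v, "missing depth"))
            continue
        if v.total_depth > min_total and v.alt_depth > min_alt:
            out.append(v)
        elif dropped is not None:
            dropped.append((v, f"depth {v.total_depth}/{v.alt_depth}"))
    return out


def exclude_regions(calls, regions: ExclusionRegions) -> list[VariantCall]:
    """Drop calls inside repeat/subtelomeric exclusion intervals."""
    return [v for v in calls if not regions.contains(v.chrom, v.pos)]


def denovo_pipeline(calls_a, calls_b, founder_variants, regions: ExclusionRegions,
                    min_total: int = 10, min_alt: int = 6, depth_from: str = "a",
                    allele_aware: bool = True,
                    ) -> tuple[list[VariantCall], pd.DataFrame]:
    """Full filter chain; returns survivors plus a per-stage attrition report."""
    stages = []
    calls = intersect_callers(calls_a, calls_b, depth_from=depth_from)
    stages.append(("intersect", len(calls_a), len(calls)))
    after = subtract_founders(calls, founder_variants, allele_aware=allele_aware)
    stages.append(("founder_subtraction", len(calls), len(after)))
    calls = after
    after = depth_filter(calls, min_total=min_total, min_alt=min_alt)
    stages.append(("depth_filter", len(calls), len(after)))
    calls = after
    after = exclude_regions(calls, regions)
    stages.append(("region_exclusion", len(calls), len(after)))
    report = pd.DataFrame(stages, columns=["stage", "n_in", "n_out"])
    return after, report


def annotate_genes(calls, gff_path) -> pd.DataFrame:
    """Label calls with the gene intervals they fall in (GFF3 overlap).

    A lightweight stand-in for consequence annotation: reports gene
    overlap only, no effect prediction.  Uses `gene` features; the label
    comes from the Name= or ID= attribute.
    """
    genes: dict[str, list[tuple[int, int, str]]] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            name = attrs.get("Name", attrs.get("ID", "?"))
            genes.setdefault(parts[0], []).append(
                (int(parts[3]), int(parts[4]), name))
    rows = []
    for v in calls:
        hits = [name for start, end, name in genes.get(v.chrom, ())
                if start <= v.pos <= end]  # GFF coordinates are 1-based closed
        rows.append((v.chrom, v.pos, v.ref, v.alt,
                     ",".join(hits) if hits else "intergenic"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene"])


def recurrence_report(calls_by_sample: dict[str, list[VariantCall]],
                      min_samples: int = 2) -> pd.DataFrame:
    """Flag variants observed in >= min_samples replicas/time points."""
    seen: dict[tuple, list[str]] = {}
    for sample, calls in calls_by_sample.items():
        for v in calls:
            seen.setdefault(v.key, []).append(sample)
    rows = [(k[0], k[1], k[2], k[3], len(s), ",".join(sorted(s)))
            for k, s in seen.items() if len(s) >= min_samples]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "n_samples", "samples"])


def packaged_fixture_paths() -> dict[str, str]:
    """Paths of the bundled hand-constructed 12-variant filter fixture."""
    from importlib.resources import files

    root = files("driftmap") / "data" / "denovo_fixture"
    return {"caller_a": str(root / "caller_a.vcf"),
            "caller_b": str(root / "caller_b.vcf"),
            "founders": str(root / "founders.vcf"),
            "exclude": str(root / "exclude_ends.bed")}


# --------------------------------------------------------------------------
# VCF I/O (plain or bgzipped VCF v4.x via pysam)


def read_vcf_calls(path, caller: str = "", pass_only: bool = True,
                   ) -> list[VariantCall]:
    """Read biallelic records of a VCF into VariantCall objects.

    Total depth from INFO/DP or FORMAT DP of the first sample; alt depth
    from FORMAT AD (second field) or INFO/AO when present.
    """
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        has_dp = "DP" in vf.header.info
        has_ao = "AO" in vf.header.info
        for rec in vf:
            if pass_only and rec.filter.keys() not in ([], ["PASS"], ["."]):
                continue
            for alt in rec.alts or ():
                total = rec.info.get("DP") if has_dp else None
                alt_d = rec.info.get("AO") if has_ao else None
                if isinstance(alt_d, tuple):
                    alt_d = alt_d[0]
                if rec.samples:
                    smp = rec.samples[0]
                    if total is None:
                        total = smp.get("DP")
                    if alt_d is None and smp.get("AD") is not None:
                        alt_d = smp["AD"][1]
                calls.append(VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    total_depth=None if total is None else int(total),
                    alt_depth=None if alt_d is None else int(alt_d),
                    caller=caller))
    return calls


def write_vcf_calls(calls, path, source: str = "driftmap-denovo") -> None:
    """Write surviving calls as a minimal VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            info = f"DP={v.total_depth};AO={v.alt_depth}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
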