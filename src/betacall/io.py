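"""Readers and writers for allele-count tables, site annotations, exclusion
BED regions, gold-standard genotypes, and the output VCF.

Conventions: site positions are 1-based (VCF convention) everywhere in this
package; BED files are 0-based half-open per the BED standard and converted
on read.  Sites are identified throughout by the key ``chrom:pos:ref:alt``.
Parsers reject invariant-violating rows (e.g. n_alt > n_total) rather than
silently coercing them.

Allele-count extraction from alignments is upstream of this package: the
counts-table contract (TSV with columns chrom, pos, ref, alt, n_alt,
n_total and optionally eaf) decouples the genotyper from any particular
aligner or pileup tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .calling import GenotypeCall
from .core import AlleleCount

log = logging.getLogger(__name__)

__all__ = [
    "SiteAnnotation",
    "site_id",
    "parse_site_id",
    "read_counts_table",
    "read_site_annotations",
    "write_counts_table",
    "read_bed",
    "filter_sites",
    "read_truth_genotypes",
    "write_calls_vcf",
    "write_calls_tsv",
    "read_calls_tsv",
]

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "n_alt", "n_total"]
_BASES = {"A", "C", "G", "T"}


def site_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def parse_site_id(sid: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = sid.rsplit(":", 3)
    return chrom, int(pos), ref, alt


@dataclass(frozen=True)
class SiteAnnotation:
    """Biallelic SNP site with an optional effect allele frequency."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.site_id}: ref and alt alleles identical")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"{self.site_id}: non-SNP alleles {self.ref}/{self.alt}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.site_id}: EAF {self.eaf} outside [0, 1]")

    @property
    def site_id(self) -> str:
        return site_id(self.chrom, self.pos, self.ref, self.alt)


def _read_counts_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("pos", "n_alt", "n_total"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} must be integer")
    bad = df.index[df["n_alt"] > df["n_total"]]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{path}: n_alt > n_total at data line {row + 2} "
            f"({df.loc[row, 'chrom']}:{df.loc[row, 'pos']})"
        )
    if df[["chrom", "pos", "ref", "alt"]].duplicated().any():
        dup = df[df[["chrom", "pos", "ref", "alt"]].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated site {dup['chrom']}:{dup['pos']}")
    return df


def read_counts_table(path) -> list[AlleleCount]:
    """Read a TSV of per-site allele counts (chrom, pos, ref, alt, n_alt,
    n_total; order preserved)."""
    df = _read_counts_frame(path)
    return [
        AlleleCount(site_id(r.chrom, r.pos, r.ref, r.alt), int(r.n_alt), int(r.n_total))
        for r in df.itertuples(index=False)
    ]


def read_site_annotations(path) -> list[SiteAnnotation]:
    """Read site annotations (ref/alt alleles, optional ``eaf`` column) from
    a counts table or a site list with the same leading columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    has_eaf = "eaf" in df.columns
    return [
        SiteAnnotation(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            eaf=(None if not has_eaf or pd.isna(r.eaf) else float(r.eaf)),
        )
        for r in df.itertuples(index=False)
    ]


def write_counts_table(path, counts: list[AlleleCount], eaf: dict | None = None) -> None:
    rows = []
    for c in counts:
        chrom, pos, ref, alt = parse_site_id(c.site_id)
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "n_alt": c.n_alt,
            "n_total": c.n_total,
        }
        if eaf is not None:
            row["eaf"] = eaf.get(c.site_id)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED exclusion regions and site filters
# ---------------------------------------------------------------------------


def read_bed(path) -> dict[str, IntervalTree]:
    """Read BED intervals (0-based, half-open) into per-chromosome interval
    trees keyed for 0-based point queries."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from e
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def filter_sites(
    sites: list[SiteAnnotation],
    counts: list[AlleleCount],
    min_eaf: float = 0.01,
    exclude: dict[str, IntervalTree] | None = None,
) -> list[AlleleCount]:
    """Apply the standard site filters to a count set.

    Keeps counts whose annotated EAF is strictly greater than ``min_eaf``
    (sites with no EAF annotation are kept) and whose 1-based position does
    not fall inside any exclusion interval (regions of known mapping bias).
    """
    ann = {s.site_id: s for s in sites}
    kept = []
    n_eaf = n_bed = 0
    for c in counts:
        s = ann.get(c.site_id)
        if s is None:
            raise KeyError(f"{c.site_id}: no site annotation")
        if s.eaf is not None and not s.eaf > min_eaf:
            n_eaf += 1
            continue
        if exclude is not None:
            tree = exclude.get(s.chrom)
            if tree is not None and tree.overlaps_point(s.pos - 1):
                n_bed += 1
                continue
        kept.append(c)
    log.info(
        "filter_sites: kept %d of %d (removed %d by EAF <= %s, %d in excluded regions)",
        len(kept), len(counts), n_eaf, min_eaf, n_bed,
    )
    return kept


# ---------------------------------------------------------------------------
# Gold-standard genotypes
# ---------------------------------------------------------------------------


def read_truth_genotypes(path, format: str = "vcf", sample: str | None = None) -> dict[str, int]:
    """Read gold-standard genotypes into ``{site_id: g}`` with g the
    alt-allele count.

    VCF: biallelic SNP records of one sample (the first unless ``sample``
    is given); half-missing or non-diploid genotypes and multi-allelic
    records are skipped (counted in a log message).  Truth sets lacking
    hom-ref entries are fine — absent sites are simply never compared.

    TSV: columns chrom, pos, ref, alt, genotype (0/1/2).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        out = {}
        for r in df.itertuples(index=False):
            g = int(r.genotype)
            if g not in (0, 1, 2):
                raise ValueError(f"{path}: genotype {g} not in {{0,1,2}}")
            out[site_id(r.chrom, r.pos, r.ref, r.alt)] = g
        return out
    if format != "vcf":
        raise ValueError(f"unknown truth format {format!r}")

    import pysam

    out = {}
    n_skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        sname = sample if sample is not None else samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            gt = rec.samples[sname].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                n_skipped += 1
                continue
            if any(a not in (0, 1) for a in gt):
                n_skipped += 1
                continue
            out[site_id(rec.chrom, rec.pos, ref, alt)] = int(sum(gt))
    if n_skipped:
        log.info("read_truth_genotypes: skipped %d records", n_skipped)
    return out


# ---------------------------------------------------------------------------
# Call output (VCF + TSV mirror)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=betacall
##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard genotype call">
##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior probabilities for 0/0, 0/1, 1/1">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternative allele dosage">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""

_GT_STRING = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _format_gp(probs) -> str:
    """GP probabilities to 4 decimals, renormalized to sum exactly to 1
    after rounding (the largest entry absorbs the residual)."""
    q = [round(float(p), 4) for p in probs]
    q[max(range(3), key=lambda i: probs[i])] += round(1.0 - sum(q), 4)
    return ",".join(f"{v:.4f}" for v in q)


def write_calls_vcf(
    calls: list[GenotypeCall],
    sites: list[SiteAnnotation],
    sample_name: str,
    path,
) -> None:
    """Write genotype calls as a single-sample VCF 4.2 with GT:GP:DS:DP."""
    ann = {s.site_id: s for s in sites}
    recs = []
    for c in calls:
        s = ann.get(c.site_id)
        if s is None:
            raise KeyError(f"{c.site_id}: no site annotation for VCF output")
        recs.append((s, c))
    recs.sort(key=lambda sc: (sc[0].chrom, sc[0].pos))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(s.chrom for s, _ in recs):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_name}\n"
        )
        for s, c in recs:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\t"
                f"GT:GP:DS:DP\t{_GT_STRING[c.hard_call]}:{_format_gp(c.probs)}:"
                f"{c.dosage:.4f}:{c.n_total}\n"
            )


def write_calls_tsv(calls: list[GenotypeCall], path) -> None:
    rows = []
    for c in calls:
        chrom, pos, ref, alt = parse_site_id(c.site_id)
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "n_alt": c.n_alt,
                "n_total": c.n_total,
                "p_g0": f"{c.probs[0]:.6g}",
                "p_g1": f"{c.probs[1]:.6g}",
                "p_g2": f"{c.probs[2]:.6g}",
                "dosage": f"{c.dosage:.6g}",
                "hard_call": "." if c.hard_call is None else c.hard_call,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[GenotypeCall]:
    import numpy as np

    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "hard_call": str}
    )
    out = []
    for r in df.itertuples(index=False):
        probs = np.array([float(r.p_g0), float(r.p_g1), float(r.p_g2)])
        out.append(
            GenotypeCall(
                site_id=site_id(r.chrom, r.pos, r.ref, r.alt),
                probs=probs,
                dosage=float(r.dosage),
                hard_call=None if r.hard_call == "." else int(r.hard_call),
                n_alt=int(r.n_alt),
                n_total=int(r.n_total),
            )
        )
    return out
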