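"""Pooled-variant input, quality/depth filtering and per-site SNP-index.

In bulked segregant analysis two DNA pools are sequenced: the H-pool from
the 30 highest- and the L-pool from the 30 lowest-exertion F2 plants.  At
every site where the cross parents carry different alleles, the SNP-index
of a pool is the fraction of its reads carrying the mutant-parent allele,
and

    delta = index_L - index_H

is near 0 away from the causal locus and rises toward +1 around a
recessive locus driving the low phenotype (the L-pool is then fixed for
the mutant allele while the H-pool segregates).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

POOL_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "qual", "depth_h", "alt_h", "depth_l", "alt_l",
]


class VariantFormatError(ValueError):
    """Raised when a variant record lacks required annotations."""


@dataclass(frozen=True)
class SnpObservation:
    """One biallelic parent-polymorphic site with per-pool read counts.

    ``alt_h`` / ``alt_l`` count reads carrying the mutant-parent allele in
    the high- and low-exertion bulk respectively, whatever that allele is
    relative to the reference.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_quality: float
    depth_h: int
    alt_h: int
    depth_l: int
    alt_l: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if not (0 <= self.alt_h <= self.depth_h):
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_h={self.alt_h} outside "
                f"[0, depth_h={self.depth_h}]")
        if not (0 <= self.alt_l <= self.depth_l):
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_l={self.alt_l} outside "
                f"[0, depth_l={self.depth_l}]")


@dataclass(frozen=True)
class SnpIndexRecord:
    """Per-site SNP-index in each pool plus their difference.

    Carries the per-pool depths as well so downstream window statistics can
    look up the depth-matched null band.
    """

    chrom: str
    pos: int
    index_h: float
    index_l: float
    delta: float
    depth_h: int
    depth_l: int


def snp_index(depth: int, alt: int) -> float:
    """Fraction of a pool's reads carrying the tracked allele at one site."""
    if depth < 1:
        raise ValueError(f"SNP-index undefined at depth {depth}; filter such sites first")
    if not (0 <= alt <= depth):
        raise ValueError(f"alt count {alt} outside [0, {depth}]")
    return alt / depth


def delta_index(index_h: float, index_l: float) -> float:
    """L-pool index minus H-pool index."""
    for name, v in (("index_h", index_h), ("index_l", index_l)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return index_l - index_h


def compute_index_records(observations: Iterable[SnpObservation]) -> list[SnpIndexRecord]:
    """SNP-index per pool and delta for every (already filtered) site."""
    out = []
    for o in observations:
        ih = snp_index(o.depth_h, o.alt_h)
        il = snp_index(o.depth_l, o.alt_l)
        out.append(
            SnpIndexRecord(
                chrom=o.chrom, pos=o.pos, index_h=ih, index_l=il,
                delta=delta_index(ih, il), depth_h=o.depth_h, depth_l=o.depth_l,
            )
        )
    return out


def filter_snps(
    observations: Sequence[SnpObservation],
    min_quality: float = 20.0,
    min_depth: int = 4,
    max_depth: int = 32,
    pools: str = "both",
) -> list[SnpObservation]:
    """Apply the site-quality and read-depth filters.

    Sites with quality below ``min_quality`` are dropped, as are sites
    whose depth falls outside ``[min_depth, max_depth]`` — bounds
    inclusive, since the exclusion rule is strictly "< min" / "> max".
    ``pools`` selects where the depth bounds apply: ``"both"`` (default,
    symmetric), ``"h"`` or ``"l"``.  Input order is preserved and the
    removal tally per rule is logged.
    """
    if min_depth > max_depth:
        raise ValueError(f"min_depth {min_depth} > max_depth {max_depth}")
    if min_quality < 0 or min_depth < 1:
        raise ValueError("thresholds must be positive")
    if pools not in ("both", "h", "l"):
        raise ValueError(f"pools must be 'both', 'h' or 'l', got {pools!r}")

    kept: list[SnpObservation] = []
    n_qual = n_depth = 0
    for o in observations:
        if o.site_quality < min_quality:
            n_qual += 1
            continue
        depths = []
        if pools in ("both", "h"):
            depths.append(o.depth_h)
        if pools in ("both", "l"):
            depths.append(o.depth_l)
        if any(d < min_depth or d > max_depth for d in depths):
            n_depth += 1
            continue
        kept.append(o)
    log.info(
        "filter_snps: kept %d / %d sites (removed %d by quality < %g, %d by depth outside [%d, %d] in pool(s) %s)",
        len(kept), len(observations), n_qual, min_quality, n_depth,
        min_depth, max_depth, pools,
    )
    return kept


def flip_orientation(obs: SnpObservation) -> SnpObservation:
    """Re-orient a site to track the opposite parent's allele."""
    return replace(
        obs,
        ref_allele=obs.alt_allele,
        alt_allele=obs.ref_allele,
        alt_h=obs.depth_h - obs.alt_h,
        alt_l=obs.depth_l - obs.alt_l,
    )


# ---------------------------------------------------------------------------
# input readers

def load_pool_variants(
    source: str | Path,
    high_sample: str | None = None,
    low_sample: str | None = None,
    mutant_parent: str | None = None,
    wild_parent: str | None = None,
) -> list[SnpObservation]:
    """Read pooled variants from a VCF or an allele-count table.

    Files ending in ``.vcf`` / ``.vcf.gz`` are parsed as VCF with per-sample
    allele depths (``AD``); anything else is read as a tab-separated table
    with columns ``chrom pos ref alt qual depth_h alt_h depth_l alt_l``
    already oriented to the mutant-parent allele.
    """
    source = Path(source)
    if source.suffix == ".vcf" or source.name.endswith(".vcf.gz"):
        if high_sample is None or low_sample is None:
            raise ValueError("VCF input requires high_sample and low_sample names")
        return load_vcf(source, high_sample, low_sample, mutant_parent, wild_parent)
    return load_allele_count_table(source)


def load_allele_count_table(path: str | Path) -> list[SnpObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(POOL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise VariantFormatError(f"{path}: missing columns {sorted(missing)}")
    obs = []
    for row in df.itertuples(index=False):
        for field in ("depth_h", "alt_h", "depth_l", "alt_l"):
            if pd.isna(getattr(row, field)):
                raise VariantFormatError(
                    f"{path}: missing {field} at {row.chrom}:{row.pos}")
        obs.append(
            SnpObservation(
                chrom=str(row.chrom), pos=int(row.pos),
                ref_allele=str(row.ref), alt_allele=str(row.alt),
                site_quality=float(row.qual),
                depth_h=int(row.depth_h), alt_h=int(row.alt_h),
                depth_l=int(row.depth_l), alt_l=int(row.alt_l),
            )
        )
    return obs


def load_vcf(
    path: str | Path,
    high_sample: str,
    low_sample: str,
    mutant_parent: str | None = None,
    wild_parent: str | None = None,
) -> list[SnpObservation]:
    """Read bulk allele depths from a VCF, oriented to the mutant parent.

    When parent samples are named, only sites where the two parents are
    opposite homozygotes are kept (the parent-polymorphism rule) and the
    tracked allele is the mutant parent's.  Without parent columns every
    biallelic record is accepted and the ALT allele is tracked.
    Multiallelic records are skipped with a logged count; a record whose
    bulk AD is missing raises :class:`VariantFormatError` naming the site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in filter(None, (high_sample, low_sample, mutant_parent, wild_parent)):
        if name not in samples:
            raise VariantFormatError(f"{path}: sample {name!r} not in VCF ({samples})")
    idx_h, idx_l = samples.index(high_sample), samples.index(low_sample)
    idx_m = samples.index(mutant_parent) if mutant_parent else None
    idx_w = samples.index(wild_parent) if wild_parent else None

    obs: list[SnpObservation] = []
    n_multi = n_nonpoly = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise VariantFormatError(f"{path}: no AD field at {v.CHROM}:{v.POS}")

        mutant_is_alt = True
        if idx_m is not None:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt_m = v.gt_types[idx_m]
            if gt_m not in (0, 3):
                n_nonpoly += 1
                continue
            if idx_w is not None:
                gt_w = v.gt_types[idx_w]
                if gt_w not in (0, 3) or gt_w == gt_m:
                    n_nonpoly += 1
                    continue
            mutant_is_alt = gt_m == 3

        counts = {}
        for pool, i in (("h", idx_h), ("l", idx_l)):
            ref_n, alt_n = int(ad[i][0]), int(ad[i][1])
            if ref_n < 0 or alt_n < 0:
                raise VariantFormatError(
                    f"{path}: missing allele depth for pool sample at {v.CHROM}:{v.POS}")
            counts[pool] = (ref_n + alt_n, alt_n if mutant_is_alt else ref_n)
        obs.append(
            SnpObservation(
                chrom=v.CHROM, pos=v.POS,
                ref_allele=v.REF if mutant_is_alt else v.ALT[0],
                alt_allele=v.ALT[0] if mutant_is_alt else v.REF,
                site_quality=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth_h=counts["h"][0], alt_h=counts["h"][1],
                depth_l=counts["l"][0], alt_l=counts["l"][1],
            )
        )
    if n_multi or n_nonpoly:
        log.info("load_vcf: skipped %d multiallelic and %d non-parent-polymorphic sites",
                 n_multi, n_nonpoly)
    return obs


# ---------------------------------------------------------------------------
# output

def index_table(records: Iterable[SnpIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos, "index_h": r.index_h,
             "index_l": r.index_l, "delta": r.delta,
             "depth_h": r.depth_h, "depth_l": r.depth_l}
            for r in records
        ],
        columns=["chrom", "pos", "index_h", "index_l", "delta", "depth_h", "depth_l"],
    )


def write_index_table(records: Iterable[SnpIndexRecord], path: str | Path) -> None:
    index_table(records).to_csv(path, sep="\t", index=False)
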