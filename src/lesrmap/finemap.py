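"""Classical linkage distances and recombinant-based fine mapping.

Among the recessive (low-exertion, genotypically aa) F2 plants, every
gamete is informative: a plant heterozygous at a marker carries one
recombinant gamete there, a plant homozygous for the non-mutant parent
carries two.  The marker-to-locus map distance in centimorgans is then
simply the recombinant-gamete percentage,

    cM = 100 * (n_single + 2 * n_double) / (2 * n_plants).

Fine mapping intersects the recombinant plants' breakpoints: markers where
a recessive plant is not homozygous mutant exclude the locus beyond the
breakpoint, so the locus is confined between the innermost fully-mutant
markers adjacent to observed breakpoints on either side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up

log = logging.getLogger(__name__)

GENOTYPE_CODES = {"A", "H", "B"}  # A: mutant hom, H: het, B: other-parent hom
MISSING_CODES = {"NA", "-", ""}


@dataclass(frozen=True)
class MarkerDef:
    """A PCR marker with its physical position (primers carried, not used)."""

    name: str
    chrom: str
    pos: int  # 1-based bp
    fwd_primer: str = ""
    rev_primer: str = ""


@dataclass(frozen=True)
class CrossoverCounts:
    """Single/double-crossover plant tallies at one marker in the recessive panel."""

    marker: str
    n_single: int
    n_double: int
    n_plants: int


@dataclass(frozen=True)
class RecombinantGenotype:
    """One recessive plant's genotype codes across the ordered marker panel.

    ``codes[i]`` corresponds to the i-th panel marker and is ``"A"``
    (mutant-parent homozygote), ``"H"`` (heterozygote), ``"B"``
    (other-parent homozygote) or ``None`` (missing).
    """

    plant_id: str
    codes: tuple
    phenotype: str = "low"


@dataclass(frozen=True)
class IntervalCall:
    left: MarkerDef
    right: MarkerDef
    length_mb: float
    internal_markers: tuple


@dataclass(frozen=True)
class CandidateVariantRow:
    """One candidate-interval variant: per-line alleles at a position in a gene."""

    gene_id: str
    pos: int
    alleles: Mapping[str, str]
    variant_class: str = ""
    annotation: str = ""


def map_distance(counts: CrossoverCounts) -> float:
    """Marker-locus map distance (cM) from crossover tallies, two decimals.

    Single-crossover plants contribute one recombinant gamete at the
    marker, double-crossover plants two, out of ``2 * n_plants`` gametes.
    The raw recombinant-gamete percentage is reported as cM without a map
    function (fine-mapping distances are small enough that the correction
    is below the printed precision).
    """
    if counts.n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    if counts.n_single < 0 or counts.n_double < 0:
        raise ValueError("crossover counts must be non-negative")
    if counts.n_single + counts.n_double > counts.n_plants:
        raise ValueError(
            f"{counts.marker}: crossover plants ({counts.n_single}+{counts.n_double}) "
            f"exceed population size {counts.n_plants}")
    cm = 100.0 * (counts.n_single + 2 * counts.n_double) / (2.0 * counts.n_plants)
    return round_half_up(cm, 2)


def _split_pattern(plant: RecombinantGenotype):
    """Indices (first_A, last_A) of the plant's mutant-homozygous block.

    A recessive plant's known codes must read as a possibly empty non-A
    prefix, a block of A, and a possibly empty non-A suffix; anything else
    (no A at all, or an interior non-A) is inconsistent with a single
    recessive locus and returns None.
    """
    known = [(i, c) for i, c in enumerate(plant.codes) if c is not None]
    a_idx = [i for i, c in known if c == "A"]
    if not a_idx:
        return None
    first_a, last_a = a_idx[0], a_idx[-1]
    for i, c in known:
        if first_a <= i <= last_a and c != "A":
            return None
        if (i < first_a or i > last_a) and c == "A":
            return None
    return first_a, last_a


def infer_interval(
    panel: Sequence[MarkerDef],
    plants: Iterable[RecombinantGenotype],
) -> IntervalCall:
    """Intersect recombinant breakpoints into the tightest flanking interval.

    For each plant with a left-arm recombination the locus must lie at or
    right of the first mutant-homozygous marker after the breakpoint;
    symmetrically on the right arm.  The reported interval is flanked by
    the max of the left bounds and the min of the right bounds; with no
    recombinants it spans the whole panel.

    Raises ``ValueError`` listing the offending plants if any genotype
    pattern is inconsistent with a single recessive locus, or if the
    bounds cross.
    """
    if len(panel) < 2:
        raise ValueError("need at least 2 markers to bound an interval")
    positions = [m.pos for m in panel]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("panel marker positions must be strictly increasing")

    left_idx, right_idx = 0, len(panel) - 1
    left_holder = right_holder = None
    bad: list[str] = []
    plant_list = list(plants)
    for p in plant_list:
        if len(p.codes) != len(panel):
            raise ValueError(
                f"plant {p.plant_id!r}: {len(p.codes)} codes for {len(panel)} markers")
        split = _split_pattern(p)
        if split is None:
            bad.append(p.plant_id)
            continue
        first_a, last_a = split
        if first_a > left_idx:
            left_idx, left_holder = first_a, p.plant_id
        if last_a < right_idx:
            right_idx, right_holder = last_a, p.plant_id
    if bad:
        raise ValueError(
            f"genotypes inconsistent with a recessive locus for plant(s): {bad}")
    if left_idx > right_idx:
        raise ValueError(
            "no consistent interval: left bound from plant "
            f"{left_holder!r} lies beyond right bound from plant {right_holder!r}")

    left, right = panel[left_idx], panel[right_idx]
    internal = tuple(m.name for m in panel[left_idx + 1:right_idx])
    call = IntervalCall(
        left=left, right=right,
        length_mb=round_half_up((right.pos - left.pos) / 1e6, 2),
        internal_markers=internal,
    )
    log.info(
        "fine-mapping interval: %s (%d) .. %s (%d), %.2f Mb, zero-recombinant internal markers: %s",
        left.name, left.pos, right.name, right.pos, call.length_mb,
        ", ".join(internal) or "none",
    )
    return call


def candidate_gene_filter(
    rows: Iterable[CandidateVariantRow],
    line_a: str,
    line_b: str,
) -> set:
    """Genes whose alleles differ between two lines at any listed position."""
    genes: set = set()
    n_rows = 0
    for row in rows:
        n_rows += 1
        for line in (line_a, line_b):
            if line not in row.alleles:
                raise ValueError(
                    f"unknown line {line!r}; available: {sorted(row.alleles)}")
        if row.alleles[line_a] != row.alleles[line_b]:
            genes.add(row.gene_id)
    log.info("candidate_gene_filter: %d distinct gene(s) differ between %s and %s "
             "across %d variant rows", len(genes), line_a, line_b, n_rows)
    return genes


# ---------------------------------------------------------------------------
# table I/O

def load_marker_panel(path: str | Path) -> list[MarkerDef]:
    """Read a marker panel TSV (name, chrom, pos, fwd_primer, rev_primer)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    markers = [
        MarkerDef(
            name=str(r.name_), chrom=str(r.chrom), pos=int(r.pos),
            fwd_primer=str(getattr(r, "fwd_primer", "")),
            rev_primer=str(getattr(r, "rev_primer", "")),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return markers


def load_genotype_matrix(
    path: str | Path, panel: Sequence[MarkerDef]
) -> list[RecombinantGenotype]:
    """Read a plants x markers code matrix aligned to the panel order.

    The first column is ``plant_id``, an optional ``phenotype`` column is
    honoured, and each remaining column must match a panel marker name;
    codes are A/H/B with NA (or '-') for missing.  The A/H/B reading in
    use (A mutant homozygote, H heterozygote, B other-parent homozygote)
    is logged once per load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    marker_names = [m.name for m in panel]
    missing = set(marker_names) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: genotype matrix lacks marker column(s) {sorted(missing)}")
    log.info("genotype codes read as A=mutant-parent homozygote, H=heterozygote, "
             "B=other-parent homozygote")
    plants = []
    for _, row in df.iterrows():
        codes = []
        for name in marker_names:
            c = str(row[name]).strip()
            if c in MISSING_CODES:
                codes.append(None)
            elif c in GENOTYPE_CODES:
                codes.append(c)
            else:
                raise ValueError(
                    f"{path}: bad genotype code {c!r} for plant {row['plant_id']}")
        plants.append(
            RecombinantGenotype(
                plant_id=str(row["plant_id"]),
                codes=tuple(codes),
                phenotype=str(row["phenotype"]) if "phenotype" in df.columns else "low",
            )
        )
    return plants


def load_candidate_variants(path: str | Path) -> list[CandidateVariantRow]:
    """Read a candidate-interval variant table.

    Expected columns: ``gene_id``, ``pos``, one ``allele_<line>`` column
    per line, and optional ``variant_class`` / ``annotation``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    allele_cols = {c: c[len("allele_"):] for c in df.columns if c.startswith("allele_")}
    if not allele_cols:
        raise ValueError(f"{path}: no allele_<line> columns found")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            CandidateVariantRow(
                gene_id=str(r.gene_id), pos=int(r.pos),
                alleles={line: str(getattr(r, col)) for col, line in allele_cols.items()},
                variant_class=str(getattr(r, "variant_class", "")),
                annotation=str(getattr(r, "annotation", "")),
            )
        )
    return rows


def load_crossover_counts(path: str | Path) -> list[CrossoverCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        CrossoverCounts(
            marker=str(r.marker), n_single=int(r.n_single),
            n_double=int(r.n_double), n_plants=int(r.n_plants),
        )
        for r in df.itertuples(index=False)
    ]
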