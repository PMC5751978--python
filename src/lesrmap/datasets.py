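"""Bundled reference data for the rice low-stigma-exertion (lesr) cross.

Small published observations from the original mapping population ship
with the package as the in-repo test surface: the chromosome-10 marker
panel with physical positions, the six recombinant plants' genotype
patterns across it, the candidate-interval variant table for the three
lines (93S, lesr, 115S), the crossover tallies among the 464 recessive
F2 plants, and the per-line exertion-rate class means.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .finemap import (
    CandidateVariantRow,
    CrossoverCounts,
    MarkerDef,
    RecombinantGenotype,
    load_candidate_variants,
    load_crossover_counts,
    load_genotype_matrix,
    load_marker_panel,
)

#: F2 class counts among 2,000 plants: (high-exertion, low-exertion)
F2_CLASS_COUNTS = (1536, 464)

#: size of the recessive mapping panel used for crossover counting
RECESSIVE_PANEL_SIZE = 464


def _path(name: str):
    return resources.files("lesrmap.data").joinpath(name)


def marker_panel() -> list[MarkerDef]:
    """The seven-marker chromosome-10 fine-mapping panel."""
    with resources.as_file(_path("markers_chr10.tsv")) as p:
        return load_marker_panel(p)


def recombinant_plants() -> list[RecombinantGenotype]:
    """Genotype codes of the six recombinants across the panel."""
    with resources.as_file(_path("recombinants_chr10.tsv")) as p:
        return load_genotype_matrix(p, marker_panel())


def candidate_variants() -> list[CandidateVariantRow]:
    """Candidate-interval variants with per-line alleles (93S, lesr, 115S)."""
    with resources.as_file(_path("candidate_variants.tsv")) as p:
        return load_candidate_variants(p)


def crossover_counts() -> list[CrossoverCounts]:
    """Single/double-crossover tallies at the four SSR markers (n=464)."""
    with resources.as_file(_path("crossover_counts.tsv")) as p:
        return load_crossover_counts(p)


def exertion_class_means() -> pd.DataFrame:
    """Mean +/- SD of SSE/DSE/SE per line (lesr, 115S, 93S), percent."""
    with resources.as_file(_path("exertion_class_means.tsv")) as p:
        return pd.read_csv(p, sep="\t")
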