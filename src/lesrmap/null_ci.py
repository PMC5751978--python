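"""Monte-Carlo null bands for delta SNP-index and candidate-region calling.

Under the null hypothesis of no QTL, both bulks are random draws of
``bulk_size`` F2 plants with genotype frequencies 1/4 aa : 1/2 Aa : 1/4 AA,
so the bulk mutant-allele frequency fluctuates around 1/2 and the observed
delta around 0, with a spread that depends on bulk size and read depth.
The band tabulates empirical two-sided quantiles of simulated null deltas
per read-depth pair; windows whose mean delta exceeds the depth-matched
upper bound in sufficiently long runs become candidate regions.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .window_scan import WindowStat

#: F2 genotype frequencies (aa, Aa, AA) for a single biallelic locus.
F2_GENOTYPE_FREQS = (0.25, 0.5, 0.25)


@dataclass(frozen=True)
class NullConfig:
    """Parameters of the no-QTL simulation."""

    bulk_size: int = 30
    n_reps: int = 1_000
    level: float = 0.95
    seed: int = 0
    #: either an iterable of (depth_h, depth_l) pairs, or an int max depth
    #: that expands to the diagonal pairs (1,1)..(max,max)
    depth_grid: object = 40

    def __post_init__(self) -> None:
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")

    def depth_pairs(self) -> list[tuple[int, int]]:
        if isinstance(self.depth_grid, int):
            return [(d, d) for d in range(1, self.depth_grid + 1)]
        pairs = [(int(h), int(l)) for h, l in self.depth_grid]
        if not pairs:
            raise ValueError("depth grid is empty")
        return pairs


@dataclass
class CiBand:
    """Per-depth-pair two-sided null quantiles of delta SNP-index."""

    level: float
    bounds: dict[tuple[int, int], tuple[float, float]]

    def lookup(self, depth_h: float, depth_l: float) -> tuple[float, float]:
        """Bounds at the tabulated depth pair nearest (L1) to the query."""
        if not self.bounds:
            raise ValueError("empty band")
        key = min(self.bounds, key=lambda k: abs(k[0] - depth_h) + abs(k[1] - depth_l))
        return self.bounds[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"depth_h": h, "depth_l": l, "lower": lo, "upper": hi}
                for (h, l), (lo, hi) in sorted(self.bounds.items())
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_windows: int
    peak_delta: float


def _null_pool_index(depth: int, cfg: NullConfig, rng: np.random.Generator) -> np.ndarray:
    """Simulated null SNP-index of one pool for each replicate."""
    geno = rng.multinomial(cfg.bulk_size, F2_GENOTYPE_FREQS, size=cfg.n_reps)
    # mean mutant-allele dosage per plant is 1, 1/2, 0 for aa, Aa, AA
    freq = (geno[:, 0] + 0.5 * geno[:, 1]) / cfg.bulk_size
    alt = rng.binomial(depth, freq)
    return alt / depth


def simulate_null_delta(
    depth_h: int,
    depth_l: int,
    cfg: NullConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``cfg.n_reps`` null delta values at the given per-pool depths.

    Each replicate samples the two bulks independently from the F2
    genotype distribution, then draws binomial read counts at the given
    depth; delta is index_L minus index_H.  Deterministic for a fixed
    seed (or a caller-supplied generator).
    """
    if depth_h < 1 or depth_l < 1:
        raise ValueError("depths must be >= 1")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, depth_h, depth_l])
    idx_h = _null_pool_index(depth_h, cfg, rng)
    idx_l = _null_pool_index(depth_l, cfg, rng)
    return idx_l - idx_h


def ci_band(cfg: NullConfig) -> CiBand:
    """Tabulate the two-sided null band over the configured depth grid.

    For each depth pair the bounds are the (1-level)/2 and 1-(1-level)/2
    empirical quantiles of :func:`simulate_null_delta`.  Each pair gets an
    independent seed stream derived from ``cfg.seed``, so the band does
    not depend on grid order.
    """
    lo_q = (1.0 - cfg.level) / 2.0
    hi_q = 1.0 - lo_q
    bounds = {}
    for pair in cfg.depth_pairs():
        deltas = simulate_null_delta(pair[0], pair[1], cfg)
        lo, hi = np.quantile(deltas, [lo_q, hi_q])
        bounds[pair] = (float(lo), float(hi))
    return CiBand(level=cfg.level, bounds=bounds)


def call_regions(
    windows: Sequence[WindowStat],
    band: CiBand,
    min_run: int = 3,
    side: str = "upper",
) -> list[CandidateRegion]:
    """Candidate regions: runs of windows whose mean delta clears the band.

    A window qualifies when it is non-missing and its mean delta exceeds
    the upper bound (or falls below the lower bound with ``side="lower"``,
    for the opposite allele orientation) at the band entry nearest its
    rounded mean per-pool depths.  Maximal runs of at least ``min_run``
    consecutive qualifying windows are merged across their step overlaps
    and reported with outer 1-based bounds.
    """
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    regions: list[CandidateRegion] = []
    run: list[WindowStat] = []

    def flush() -> None:
        if len(run) >= min_run:
            regions.append(
                CandidateRegion(
                    chrom=run[0].chrom,
                    start=min(w.start for w in run),
                    end=max(w.end for w in run),
                    n_windows=len(run),
                    peak_delta=max(w.mean_delta for w in run),
                )
            )
        run.clear()

    prev_chrom = None
    for w in windows:
        if w.chrom != prev_chrom:
            flush()
            prev_chrom = w.chrom
        qualifies = False
        if not w.missing:
            lo, hi = band.lookup(round(w.mean_depth_h), round(w.mean_depth_l))
            qualifies = w.mean_delta > hi if side == "upper" else w.mean_delta < lo
        if qualifies:
            run.append(w)
        else:
            flush()
    flush()
    return regions


def regions_table(regions: Iterable[CandidateRegion]) -> pd.DataFrame:
    """BED-like frame: 0-based half-open columns first, 1-based mirrors after."""
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "start0": r.start - 1, "end0": r.end,
             "start1": r.start, "end1": r.end,
             "n_windows": r.n_windows, "peak_delta": r.peak_delta}
            for r in regions
        ],
        columns=["chrom", "start0", "end0", "start1", "end1", "n_windows", "peak_delta"],
    )


def write_regions(regions: Iterable[CandidateRegion], path: str | Path) -> None:
    regions_table(regions).to_csv(path, sep="\t", index=False)
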