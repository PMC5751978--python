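"""Stigma-exertion phenotype quantitation and Mendelian segregation testing.

Rice spikelets carry two stigmas.  After flowering a spikelet may expose
one stigma (single exposure), both (double exposure) or neither.  Per
panicle the three standard rates are

    SSE% = 100 * Ns / (2 * S)          single-exposure rate
    DSE% = 100 * 2 * Nd / (2 * S)      double-exposure rate
    SE%  = SSE% + DSE%                 total exertion rate

where Ns and Nd are the numbers of single- and double-exposure spikelets
and S is the number of spikelets on the panicle: each rate is the fraction
of the panicle's 2*S stigmas that are exposed.

An F2 from a low-exertion mutant crossed to a normal-exertion line splits
into a high and a low class at SE% = 25; a 3:1 high:low ratio indicates a
single recessive locus, tested here by Pearson chi-square with 1 df.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Tuple

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from ._util import round_half_up

log = logging.getLogger(__name__)

#: SE% boundary separating the low- and high-exertion phenotype classes.
DEFAULT_SE_THRESHOLD = 25.0


@dataclass(frozen=True)
class SpikeletCount:
    """Raw spikelet tallies for one plant's panicle."""

    plant_id: str
    n_single: int
    n_double: int
    n_spikelets: int

    def __post_init__(self) -> None:
        if self.n_spikelets <= 0:
            raise ValueError(
                f"plant {self.plant_id!r}: n_spikelets must be positive, "
                f"got {self.n_spikelets}"
            )
        if self.n_single < 0 or self.n_double < 0:
            raise ValueError(f"plant {self.plant_id!r}: negative spikelet count")
        if self.n_single + self.n_double > self.n_spikelets:
            raise ValueError(
                f"plant {self.plant_id!r}: n_single + n_double "
                f"({self.n_single + self.n_double}) exceeds n_spikelets "
                f"({self.n_spikelets})"
            )


@dataclass(frozen=True)
class ExertionRates:
    """Per-plant exertion rates in percent; ``se == sse + dse`` exactly."""

    sse: float
    dse: float
    se: float


@dataclass(frozen=True)
class SegregationResult:
    n_high: int
    n_low: int
    ratio_low_to_high: float
    chi2: float
    p_value: float
    consistent_with_3_1: bool


def compute_exertion_rates(counts: SpikeletCount) -> ExertionRates:
    """Exertion rates in percent from one panicle's spikelet tallies.

    A single-exposure spikelet exposes one of its two stigmas, a
    double-exposure spikelet both, so the exposed-stigma fraction is
    (Ns + 2*Nd) / (2*S).  ``se`` is computed as ``sse + dse`` so the
    additive identity holds exactly in floating point.
    """
    denom = 2.0 * counts.n_spikelets
    sse = 100.0 * counts.n_single / denom
    dse = 100.0 * (2.0 * counts.n_double) / denom
    return ExertionRates(sse=sse, dse=dse, se=sse + dse)


def percent_reduction(mutant_rate: float, wild_rate: float) -> float:
    """Relative reduction of a mutant rate against the wild type, in percent.

    Reported to two decimals (half-up).  ``wild_rate`` must be positive.
    """
    if wild_rate <= 0:
        raise ValueError(f"wild_rate must be positive, got {wild_rate}")
    return round_half_up(100.0 * (wild_rate - mutant_rate) / wild_rate, 2)


def classify_plant(se: float, threshold: float = DEFAULT_SE_THRESHOLD) -> str:
    """Assign a plant to the ``"low"`` or ``"high"`` exertion class.

    Plants strictly below the threshold are low; the boundary value itself
    is assigned to the high class (fixed convention; the threshold is
    configurable).
    """
    return "low" if se < threshold else "high"


def segregation_test(
    n_high: int,
    n_low: int,
    expected_ratio: Tuple[float, float] = (3.0, 1.0),
    yates: bool = False,
    alpha: float = 0.05,
) -> SegregationResult:
    """Pearson chi-square test of an F2 class split against a Mendelian ratio.

    Parameters
    ----------
    n_high, n_low : observed class counts (high first, matching the
        ``expected_ratio`` order).
    expected_ratio : expected high:low ratio, default 3:1 for a single
        recessive locus.
    yates : apply the Yates continuity correction. Off by default; the
        conventional comparison is the uncorrected statistic against the
        chi-square critical value with 1 df.
    alpha : significance level for the consistency verdict.
    """
    if n_high < 0 or n_low < 0:
        raise ValueError("counts must be non-negative")
    n = n_high + n_low
    if n == 0:
        raise ValueError("both counts are zero")
    rh, rl = expected_ratio
    exp_high = n * rh / (rh + rl)
    exp_low = n * rl / (rh + rl)
    stat = 0.0
    for obs, exp in ((n_high, exp_high), (n_low, exp_low)):
        dev = abs(obs - exp)
        if yates:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / exp
    p = float(_chi2_dist.sf(stat, df=1))
    ratio = round_half_up(n_low / n_high, 2) if n_high > 0 else float("inf")
    result = SegregationResult(
        n_high=n_high,
        n_low=n_low,
        ratio_low_to_high=ratio,
        chi2=stat,
        p_value=p,
        consistent_with_3_1=p > alpha,
    )
    log.info(
        "segregation: %d high : %d low (1.00:%.2f), chi2=%.3f, p=%.4f, %s 3:1 at alpha=%g",
        n_high, n_low, ratio, stat, p,
        "consistent with" if result.consistent_with_3_1 else "inconsistent with",
        alpha,
    )
    return result


# ---------------------------------------------------------------------------
# table I/O

def load_phenotypes(path: str | Path) -> list[SpikeletCount]:
    """Read a tab-separated phenotype table (plant_id, n_single, n_double,
    n_spikelets; one row per plant)."""
    df = pd.read_csv(path, sep="\t", dtype={"plant_id": str})
    required = {"plant_id", "n_single", "n_double", "n_spikelets"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    return [
        SpikeletCount(
            plant_id=row.plant_id,
            n_single=int(row.n_single),
            n_double=int(row.n_double),
            n_spikelets=int(row.n_spikelets),
        )
        for row in df.itertuples(index=False)
    ]


def rates_table(counts: Iterable[SpikeletCount]) -> pd.DataFrame:
    """Per-plant exertion rates as a plot-ready frame (percent columns)."""
    rows = []
    for c in counts:
        r = compute_exertion_rates(c)
        rows.append(
            {"plant_id": c.plant_id, "sse": r.sse, "dse": r.dse, "se": r.se,
             "phenotype_class": classify_plant(r.se)}
        )
    return pd.DataFrame(rows, columns=["plant_id", "sse", "dse", "se", "phenotype_class"])
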