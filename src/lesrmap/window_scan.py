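"""Sliding-window smoothing of per-site SNP-index profiles.

Raw per-site indices are noisy at 20-30x pooled depth; the genome scan
therefore averages them in 1 Mb windows advanced in 10 kb steps along each
chromosome, and the candidate-region caller operates on these window means.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .snp_index import SnpIndexRecord

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_STEP_BP = 10_000
DEFAULT_MIN_SNPS = 3


@dataclass(frozen=True)
class WindowStat:
    """Summary of one sliding window.

    ``missing`` windows hold fewer than the minimum number of sites and
    carry NaN means.  ``mean_depth_h`` / ``mean_depth_l`` are the mean
    member-site read depths per pool, used downstream to look up the
    depth-matched null band.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; truncated at the chromosome end
    mid: float
    n_snps: int
    mean_h: float
    mean_l: float
    mean_delta: float
    mean_depth_h: float
    mean_depth_l: float
    missing: bool


def sliding_windows(
    records: Sequence[SnpIndexRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[WindowStat]:
    """Window means of SNP-index and delta along each chromosome.

    Windows are anchored at position 1 and advanced by ``step_bp`` up to
    the chromosome length; the terminal windows are truncated at the
    chromosome end and kept.  A window with fewer than ``min_snps``
    member sites is flagged ``missing`` with NaN means.
    """
    if chrom_lengths is None or not chrom_lengths:
        raise ValueError("chrom_lengths mapping is required")
    if not (window_bp >= step_bp >= 1):
        raise ValueError(f"need window_bp >= step_bp >= 1, got {window_bp}, {step_bp}")

    unknown = {r.chrom for r in records} - set(chrom_lengths)
    if unknown:
        raise ValueError(f"records on unknown chromosome(s): {sorted(unknown)}")

    by_chrom: dict[str, list[SnpIndexRecord]] = {c: [] for c in chrom_lengths}
    for r in records:
        by_chrom[r.chrom].append(r)

    out: list[WindowStat] = []
    for chrom, length in chrom_lengths.items():
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        # prefix sums over sites sorted by position; window mean is then a
        # difference of two prefix values
        def csum(vals):
            return np.concatenate(([0.0], np.cumsum(np.asarray(vals, dtype=float))))

        ch = csum([r.index_h for r in recs])
        cl = csum([r.index_l for r in recs])
        cd = csum([r.delta for r in recs])
        cdh = csum([r.depth_h for r in recs])
        cdl = csum([r.depth_l for r in recs])

        starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp - 1, length)
        i = np.searchsorted(pos, starts, side="left")
        j = np.searchsorted(pos, ends, side="right")
        n = j - i
        for k in range(len(starts)):
            nk = int(n[k])
            missing = nk < min_snps
            if missing:
                mh = ml = md = mdh = mdl = float("nan")
            else:
                a, b = int(i[k]), int(j[k])
                mh = (ch[b] - ch[a]) / nk
                ml = (cl[b] - cl[a]) / nk
                md = (cd[b] - cd[a]) / nk
                mdh = (cdh[b] - cdh[a]) / nk
                mdl = (cdl[b] - cdl[a]) / nk
            out.append(
                WindowStat(
                    chrom=chrom, start=int(starts[k]), end=int(ends[k]),
                    mid=(int(starts[k]) + int(ends[k])) / 2.0,
                    n_snps=nk, mean_h=mh, mean_l=ml, mean_delta=md,
                    mean_depth_h=mdh, mean_depth_l=mdl, missing=missing,
                )
            )
    return out


def window_table(windows: Iterable[WindowStat]) -> pd.DataFrame:
    """Plot-ready window table (one row per window per chromosome)."""
    return pd.DataFrame(
        [
            {"chrom": w.chrom, "start": w.start, "end": w.end, "mid": w.mid,
             "n_snps": w.n_snps, "mean_index_h": w.mean_h,
             "mean_index_l": w.mean_l, "mean_delta": w.mean_delta,
             "mean_depth_h": w.mean_depth_h, "mean_depth_l": w.mean_depth_l,
             "missing": w.missing}
            for w in windows
        ]
    )


def write_window_table(windows: Iterable[WindowStat], path: str | Path) -> None:
    window_table(windows).to_csv(path, sep="\t", index=False)
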