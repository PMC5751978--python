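"""Synthetic F2 population, extreme bulks and pooled read counts.

Generates complete, ground-truthed inputs with the statistical structure
the analysis assumes: a biparental F2 cross segregating one recessive
locus, per-plant stigma-exertion phenotypes drawn from the two observed
class distributions, bulks of the most extreme plants per tail, and
binomial pooled read counts at parent-polymorphic SNPs.

Meiosis follows the Haldane (no-interference) model: each gamete receives
a Poisson number of crossovers per chromosome proportional to its genetic
length, with breakpoints placed uniformly.  Allele 1 denotes the
mutant-parent (low-exertion) haplotype throughout, so a plant with dosage
2 at the QTL is the recessive aa class.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotype import classify_plant
from .snp_index import POOL_TABLE_COLUMNS, SnpObservation

log = logging.getLogger(__name__)

#: spikelets per simulated panicle when decomposing SE% into counts
PANICLE_SPIKELETS = 120

#: constant site quality assigned to simulated variant records (passes the
#: default quality filter; tests craft low-quality sites explicitly)
SIM_SITE_QUALITY = 228.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated mapping experiment.

    Defaults mirror the real design: an F2 of 2,000 plants segregating one
    recessive locus, low-class SE% ~ N(12.53, 2.44) and high-class
    ~ N(42.68, 3.39) (both clipped to [0, 100]), a class boundary at
    SE% = 25, bulks of the 30 most extreme plants per tail, 1,000
    segregating sites on a 20 Mb chromosome and ~24x mean pooled depth.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr10": 20_000_000})
    qtl_chrom: str = "chr10"
    qtl_pos: int = 13_800_000
    n_f2: int = 2_000
    bulk_size: int = 30
    n_sites: int = 1_000
    mean_depth: float = 24.0
    depth_dispersion: float | None = None  # None = Poisson; else NB size param
    seq_error: float = 0.002
    low_mean: float = 12.53
    low_sd: float = 2.44
    high_mean: float = 42.68
    high_sd: float = 3.39
    se_threshold: float = 25.0
    bp_per_cm: int = 400_000
    marker_offsets: Sequence[int] = (
        -800_000, -300_000, -100_000, 100_000, 300_000, 800_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must name at least one chromosome")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.qtl_chrom not in self.chrom_lengths:
            raise ValueError(f"qtl_chrom {self.qtl_chrom!r} not in chrom_lengths")
        if not (1 <= self.qtl_pos <= self.chrom_lengths[self.qtl_chrom]):
            raise ValueError("qtl_pos outside its chromosome")
        if 2 * self.bulk_size > self.n_f2:
            raise ValueError("need n_f2 >= 2 * bulk_size")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")

    def marker_positions(self) -> list[int]:
        pos = [self.qtl_pos + off for off in self.marker_offsets]
        L = self.chrom_lengths[self.qtl_chrom]
        if any(p < 1 or p > L for p in pos):
            raise ValueError("marker offsets fall outside the QTL chromosome")
        return sorted(pos)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    site_positions: dict          # chrom -> int array of site bp positions
    marker_positions: list        # bp on the QTL chromosome
    site_dosage: dict             # chrom -> (n_f2, n_sites) mutant-allele dosage
    marker_dosage: np.ndarray     # (n_f2, n_markers)
    qtl_dosage: np.ndarray        # (n_f2,)
    se: np.ndarray | None = None  # per-plant SE%, set by assign_phenotypes
    bulk_low: np.ndarray | None = None   # plant indices, set by build_bulks_and_reads
    bulk_high: np.ndarray | None = None


def simulate_gametes(
    length_bp: int,
    n_gametes: int,
    positions: np.ndarray,
    bp_per_cm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parental-origin alleles (0/1) of ``n_gametes`` gametes at ``positions``.

    Crossovers per gamete are Poisson with mean equal to the chromosome's
    genetic length in Morgans (length_bp / bp_per_cm / 100); breakpoints
    are uniform and the telomere-proximal parental origin is a fair coin.
    """
    positions = np.asarray(positions, dtype=np.int64)
    morgans = length_bp / bp_per_cm / 100.0
    n_x = rng.poisson(morgans, size=n_gametes)
    alleles = np.empty((n_gametes, len(positions)), dtype=np.int8)
    starts = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_x[g] == 0:
            alleles[g] = starts[g]
            continue
        breaks = np.sort(rng.uniform(0, length_bp, size=n_x[g]))
        flips = np.searchsorted(breaks, positions, side="left")
        alleles[g] = (starts[g] + flips) % 2
    return alleles


def simulate_f2(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Simulate the F2 population's genotypes at sites, markers and the QTL."""
    if rng is None:
        rng = np.random.default_rng(config.seed)

    total_len = sum(config.chrom_lengths.values())
    site_positions: dict[str, np.ndarray] = {}
    remaining = config.n_sites
    chroms = list(config.chrom_lengths)
    for i, chrom in enumerate(chroms):
        L = config.chrom_lengths[chrom]
        n = remaining if i == len(chroms) - 1 else int(round(config.n_sites * L / total_len))
        n = min(n, remaining)
        remaining -= n
        pos = np.sort(rng.choice(L, size=n, replace=False)) + 1
        site_positions[chrom] = pos.astype(np.int64)

    marker_pos = np.asarray(config.marker_positions(), dtype=np.int64)
    site_dosage: dict[str, np.ndarray] = {}
    marker_dosage = None
    qtl_dosage = None
    for chrom, L in config.chrom_lengths.items():
        eval_pos = site_positions[chrom]
        extra = 0
        if chrom == config.qtl_chrom:
            eval_pos = np.concatenate([eval_pos, marker_pos, [config.qtl_pos]])
            extra = len(marker_pos) + 1
        order = np.argsort(eval_pos, kind="stable")
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        gam = simulate_gametes(L, 2 * config.n_f2, eval_pos[order], config.bp_per_cm, rng)
        dosage_sorted = gam[0::2] + gam[1::2]          # (n_f2, n_eval)
        dosage = dosage_sorted[:, inv]                 # back to eval_pos order
        n_sites_c = len(site_positions[chrom])
        site_dosage[chrom] = dosage[:, :n_sites_c]
        if chrom == config.qtl_chrom:
            marker_dosage = dosage[:, n_sites_c:n_sites_c + len(marker_pos)]
            qtl_dosage = dosage[:, -1]

    truth = SimTruth(
        config=config,
        site_positions=site_positions,
        marker_positions=marker_pos.tolist(),
        site_dosage=site_dosage,
        marker_dosage=marker_dosage,
        qtl_dosage=qtl_dosage,
    )
    counts = np.bincount(qtl_dosage, minlength=3)
    log.info("simulate_f2: %d plants, QTL genotype counts AA/Aa/aa = %d/%d/%d",
             config.n_f2, counts[0], counts[1], counts[2])
    return truth


def assign_phenotypes(truth: SimTruth, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw per-plant SE% from the class distribution of the QTL genotype.

    aa plants (dosage 2) draw from the low-exertion distribution, Aa and
    AA plants from the high one (full recessivity); draws are clipped to
    [0, 100].  With the default means >8 SD apart the classes barely
    overlap, so the SE% = 25 boundary recovers the genotype classes.
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    aa = truth.qtl_dosage == 2
    se = np.where(
        aa,
        rng.normal(cfg.low_mean, cfg.low_sd, size=cfg.n_f2),
        rng.normal(cfg.high_mean, cfg.high_sd, size=cfg.n_f2),
    )
    truth.se = np.clip(se, 0.0, 100.0)
    return truth


def _se_to_spikelet_counts(se: float) -> tuple[int, int, int]:
    """Decompose an SE% into integer (n_single, n_double, n_spikelets).

    Exposed stigmas E = round(SE/100 * 2S); roughly a quarter of them sit
    on double-exposure spikelets, clamped so counts stay feasible.  The
    recomputed SE% differs from the input by less than half a point.
    """
    s = PANICLE_SPIKELETS
    e = int(round(se / 100.0 * 2 * s))
    nd = max(e // 4, e - s)
    ns = e - 2 * nd
    return ns, nd, s


@dataclass
class SimOutputs:
    """In-memory emitted tables plus the truth record."""

    observations: list
    phenotypes: pd.DataFrame
    marker_panel: pd.DataFrame
    genotype_matrix: pd.DataFrame
    truth: SimTruth


def build_bulks_and_reads(
    truth: SimTruth, rng: np.random.Generator | None = None
) -> SimOutputs:
    """Select the extreme bulks and draw pooled read counts at every site.

    Bulks are the ``bulk_size`` lowest- and highest-SE% plants.  At each
    site the pool's mutant-allele frequency is the mean allele dosage over
    its members divided by two; sequencing error flips each read's allele
    with probability ``seq_error``; depth is Poisson (or negative binomial
    when ``depth_dispersion`` is set) around ``mean_depth`` per pool.
    """
    cfg = truth.config
    if truth.se is None:
        raise ValueError("assign_phenotypes must run before build_bulks_and_reads")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])

    order = np.argsort(truth.se, kind="stable")
    truth.bulk_low = np.sort(order[:cfg.bulk_size])
    truth.bulk_high = np.sort(order[-cfg.bulk_size:])

    def draw_depth(n: int) -> np.ndarray:
        if cfg.depth_dispersion is None:
            return rng.poisson(cfg.mean_depth, size=n)
        size = cfg.depth_dispersion
        p = size / (size + cfg.mean_depth)
        return rng.negative_binomial(size, p, size=n)

    observations: list[SnpObservation] = []
    for chrom, pos in truth.site_positions.items():
        dos = truth.site_dosage[chrom]
        rows = []
        for bulk, tag in ((truth.bulk_high, "h"), (truth.bulk_low, "l")):
            freq = dos[bulk].mean(axis=0) / 2.0
            p = freq * (1 - cfg.seq_error) + (1 - freq) * cfg.seq_error
            depth = draw_depth(len(pos))
            alt = rng.binomial(depth, p)
            rows.append((depth, alt))
        (dh, ah), (dl, al) = rows
        for k in range(len(pos)):
            observations.append(
                SnpObservation(
                    chrom=chrom, pos=int(pos[k]), ref_allele="G", alt_allele="A",
                    site_quality=SIM_SITE_QUALITY,
                    depth_h=int(dh[k]), alt_h=int(ah[k]),
                    depth_l=int(dl[k]), alt_l=int(al[k]),
                )
            )

    pheno_rows = []
    for i in range(cfg.n_f2):
        ns, nd, s = _se_to_spikelet_counts(float(truth.se[i]))
        pheno_rows.append(
            {"plant_id": f"F2-{i:04d}", "n_single": ns, "n_double": nd, "n_spikelets": s})
    phenotypes = pd.DataFrame(pheno_rows)

    marker_panel = pd.DataFrame(
        [
            {"name": f"SM-{j + 1}", "chrom": cfg.qtl_chrom, "pos": int(p),
             "fwd_primer": "", "rev_primer": ""}
            for j, p in enumerate(truth.marker_positions)
        ]
    )
    code = {2: "A", 1: "H", 0: "B"}
    recessive = np.flatnonzero(truth.qtl_dosage == 2)
    geno_rows = []
    for i in recessive:
        row = {"plant_id": f"F2-{i:04d}", "phenotype": classify_plant(
            float(truth.se[i]), cfg.se_threshold)}
        for j in range(len(truth.marker_positions)):
            row[f"SM-{j + 1}"] = code[int(truth.marker_dosage[i, j])]
        geno_rows.append(row)
    genotype_matrix = pd.DataFrame(geno_rows)

    return SimOutputs(
        observations=observations, phenotypes=phenotypes,
        marker_panel=marker_panel, genotype_matrix=genotype_matrix, truth=truth,
    )


def simulate_experiment(config: SimConfig) -> SimOutputs:
    """Convenience end-to-end: genotypes, phenotypes, bulks and reads."""
    truth = simulate_f2(config)
    assign_phenotypes(truth)
    return build_bulks_and_reads(truth)


# ---------------------------------------------------------------------------
# emission

def pool_table(observations) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": o.chrom, "pos": o.pos, "ref": o.ref_allele,
             "alt": o.alt_allele, "qual": o.site_quality,
             "depth_h": o.depth_h, "alt_h": o.alt_h,
             "depth_l": o.depth_l, "alt_l": o.alt_l}
            for o in observations
        ],
        columns=POOL_TABLE_COLUMNS,
    )


def write_outputs(out: SimOutputs, outdir: str | Path) -> dict:
    """Write all emitted tables plus the truth JSON; returns path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = out.truth.config
    paths = {
        "pool_table": outdir / "pool_counts.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "marker_panel": outdir / "marker_panel.tsv",
        "genotype_matrix": outdir / "genotype_matrix.tsv",
        "truth": outdir / "truth.json",
    }
    pool_table(out.observations).to_csv(paths["pool_table"], sep="\t", index=False)
    out.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    out.marker_panel.to_csv(paths["marker_panel"], sep="\t", index=False)
    out.genotype_matrix.to_csv(paths["genotype_matrix"], sep="\t", index=False)

    cfg_dict = asdict(cfg)
    cfg_dict["chrom_lengths"] = dict(cfg.chrom_lengths)
    cfg_dict["marker_offsets"] = list(cfg.marker_offsets)
    truth_doc = {
        "config": cfg_dict,
        "qtl": {"chrom": cfg.qtl_chrom, "pos": cfg.qtl_pos},
        "qtl_dosage": out.truth.qtl_dosage.tolist(),
        "se": np.round(out.truth.se, 6).tolist(),
        "bulk_low": out.truth.bulk_low.tolist(),
        "bulk_high": out.truth.bulk_high.tolist(),
        "site_positions": {c: p.tolist() for c, p in out.truth.site_positions.items()},
        "marker_positions": list(out.truth.marker_positions),
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return {k: str(v) for k, v in paths.items()}


def write_vcf(out: SimOutputs, path: str | Path) -> None:
    """Emit the pooled counts as a minimal VCF with AD/DP fields.

    Samples ``H`` and ``L`` hold the bulk allele depths; parents ``P_WT``
    and ``P_MUT`` are written as fixed opposite homozygotes so the
    parent-polymorphism rule applies on re-read.  The mutant-parent allele
    is written as ALT, matching the simulator's orientation.
    """
    cfg = out.truth.config
    lines = ["##fileformat=VCFv4.2"]
    for chrom, L in cfg.chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={L}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP_WT\tP_MUT\tH\tL",
    ]
    for o in out.observations:
        fmt = "GT:AD:DP"
        wt = f"0/0:{30},0:30"
        mut = f"1/1:0,{30}:30"
        h = f"./.:{o.depth_h - o.alt_h},{o.alt_h}:{o.depth_h}"
        l = f"./.:{o.depth_l - o.alt_l},{o.alt_l}:{o.depth_l}"
        lines.append(
            f"{o.chrom}\t{o.pos}\t.\t{o.ref_allele}\t{o.alt_allele}\t"
            f"{o.site_quality:g}\tPASS\t.\t{fmt}\t{wt}\t{mut}\t{h}\t{l}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
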