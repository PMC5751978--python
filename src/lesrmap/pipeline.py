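"""End-to-end orchestration with a validated configuration and a manifest.

The pipeline runs simulate (optional) -> load -> filter -> index -> scan
-> band -> call -> report.  Every run appends a record to
``manifest.json`` carrying the configuration hash and the stage output
paths; deterministic stages are bit-identical across reruns with the same
configuration, stochastic ones identical under the same seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import snp_index as si
from . import window_scan as ws
from . import null_ci as nc
from . import simulate as sim
from .phenotype import load_phenotypes, rates_table, segregation_test

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults are the published analysis settings."""

    outdir: str = "lesrmap_run"
    seed: int = 0
    log_level: str = "INFO"

    # input paths; None for pool_table triggers the bundled simulation
    pool_table: str | None = None
    vcf: str | None = None
    vcf_samples: Mapping[str, str] = field(default_factory=dict)
    phenotypes: str | None = None

    simulate: bool = True
    sim: Mapping = field(default_factory=dict)  # SimConfig overrides

    min_quality: float = 20.0
    min_depth: int = 4
    max_depth: int = 32
    depth_filter_pools: str = "both"

    window_bp: int = 1_000_000
    step_bp: int = 10_000
    min_snps: int = 3
    chrom_lengths: Mapping[str, int] = field(default_factory=dict)

    bulk_size: int = 30
    n_reps: int = 1_000
    level: float = 0.95
    max_band_depth: int = 40

    min_run: int = 3
    call_side: str = "upper"

    se_threshold: float = 25.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        """Collect every schema violation before any stage runs."""
        errors = []
        if self.window_bp < self.step_bp:
            errors.append(f"window_bp ({self.window_bp}) < step_bp ({self.step_bp})")
        if self.step_bp < 1:
            errors.append("step_bp must be >= 1")
        if self.min_depth > self.max_depth:
            errors.append("min_depth > max_depth")
        if not (0.0 < self.level < 1.0):
            errors.append("level must be in (0, 1)")
        if self.n_reps < 100:
            errors.append("n_reps must be >= 100")
        if self.call_side not in ("upper", "lower"):
            errors.append("call_side must be 'upper' or 'lower'")
        if not self.simulate:
            for name in ("pool_table", "vcf"):
                p = getattr(self, name)
                if p and not Path(p).exists():
                    errors.append(f"{name} file not found: {p}")
            if not (self.pool_table or self.vcf):
                errors.append("either simulate=true or an input (pool_table/vcf) is required")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run record appended to the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, str] = {}

    chrom_lengths = dict(config.chrom_lengths)
    phenotype_path = config.phenotypes

    # stage: simulate (optional)
    if config.simulate:
        sim_cfg = sim.SimConfig(**{"seed": config.seed, "bulk_size": config.bulk_size,
                                   **dict(config.sim)})
        out = sim.simulate_experiment(sim_cfg)
        sim_paths = sim.write_outputs(out, outdir / "sim")
        stage_outputs["simulate"] = sim_paths["pool_table"]
        pool_path = sim_paths["pool_table"]
        phenotype_path = phenotype_path or sim_paths["phenotypes"]
        chrom_lengths = chrom_lengths or dict(sim_cfg.chrom_lengths)
    else:
        pool_path = config.pool_table or config.vcf

    # stage: load
    obs = si.load_pool_variants(pool_path, **dict(config.vcf_samples))
    log.info("loaded %d sites from %s", len(obs), pool_path)

    # stage: filter
    kept = si.filter_snps(
        obs, min_quality=config.min_quality, min_depth=config.min_depth,
        max_depth=config.max_depth, pools=config.depth_filter_pools)
    filtered_path = outdir / "filtered_sites.tsv"
    sim.pool_table(kept).to_csv(filtered_path, sep="\t", index=False)
    stage_outputs["filter"] = str(filtered_path)

    # stage: index
    records = si.compute_index_records(kept)
    index_path = outdir / "snp_index.tsv"
    si.write_index_table(records, index_path)
    stage_outputs["index"] = str(index_path)

    # stage: scan
    if not chrom_lengths:
        chrom_lengths = {r.chrom: max(x.pos for x in records if x.chrom == r.chrom)
                         for r in records}
    windows = ws.sliding_windows(
        records, window_bp=config.window_bp, step_bp=config.step_bp,
        min_snps=config.min_snps, chrom_lengths=chrom_lengths)
    windows_path = outdir / "windows.tsv"
    ws.write_window_table(windows, windows_path)
    stage_outputs["scan"] = str(windows_path)

    # stage: band
    null_cfg = nc.NullConfig(
        bulk_size=config.bulk_size, n_reps=config.n_reps, level=config.level,
        seed=config.seed, depth_grid=config.max_band_depth)
    band = nc.ci_band(null_cfg)
    band_path = outdir / "band.tsv"
    band.write(band_path)
    stage_outputs["band"] = str(band_path)

    # stage: call
    regions = nc.call_regions(windows, band, min_run=config.min_run,
                              side=config.call_side)
    regions_path = outdir / "regions.bed.tsv"
    nc.write_regions(regions, regions_path)
    stage_outputs["call"] = str(regions_path)

    # stage: report (segregation from phenotypes, if available)
    report: dict = {"n_regions": len(regions)}
    if phenotype_path:
        counts = load_phenotypes(phenotype_path)
        rates = rates_table(counts)
        n_low = int((rates["phenotype_class"] == "low").sum())
        n_high = len(rates) - n_low
        seg = segregation_test(n_high, n_low)
        report["segregation"] = {
            "n_high": seg.n_high, "n_low": seg.n_low,
            "ratio_low_to_high": seg.ratio_low_to_high,
            "chi2": seg.chi2, "p_value": seg.p_value,
            "consistent_with_3_1": seg.consistent_with_3_1,
        }
        rates_path = outdir / "exertion_rates.tsv"
        rates.to_csv(rates_path, sep="\t", index=False)
        stage_outputs["rates"] = str(rates_path)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1))
    stage_outputs["report"] = str(report_path)

    record = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stage_outputs,
        "regions": [dataclasses.asdict(r) for r in regions],
    }
    manifest_path = outdir / "manifest.json"
    manifest = []
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.append(record)
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return record
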