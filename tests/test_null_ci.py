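"""Monte-Carlo null band behavior and candidate-region calling."""
import numpy as np
import pytest

from lesrmap.null_ci import CandidateRegion, CiBand, NullConfig, call_regions, ci_band, simulate_null_delta
from lesrmap.window_scan import WindowStat


def make_window(i, delta, chrom="c", step=10_000, window=100_000, missing=False,
                depth=24.0):
    start = 1 + i * step
    return WindowStat(chrom=chrom, start=start, end=start + window - 1,
                      mid=start + window / 2, n_snps=0 if missing else 10,
                      mean_h=0.3, mean_l=0.3 + delta, mean_delta=delta,
                      mean_depth_h=depth, mean_depth_l=depth, missing=missing)


def test_null_delta_centred_and_bounded():
    cfg = NullConfig(n_reps=4000, seed=11)
    d = simulate_null_delta(24, 24, cfg)
    assert len(d) == 4000
    assert np.all((d >= -1.0) & (d <= 1.0))
    se = d.std(ddof=1) / np.sqrt(len(d))
    assert abs(d.mean()) < 4 * se


def test_null_delta_vanishes_at_large_bulk_and_depth():
    """Law-of-large-numbers limit: the null delta concentrates at 0 as both
    the bulk size and the read depth grow (95% of draws within 0.02)."""
    cfg = NullConfig(bulk_size=10_000, n_reps=200, seed=5)
    d = simulate_null_delta(10_000, 10_000, cfg)
    assert float(np.quantile(np.abs(d), 0.95)) < 0.02
    small = simulate_null_delta(24, 24, NullConfig(bulk_size=30, n_reps=200, seed=5))
    assert float(np.quantile(np.abs(small), 0.95)) > 0.02  # genuinely shrinks


def test_null_delta_deterministic_under_seed():
    cfg = NullConfig(n_reps=500, seed=42)
    assert np.array_equal(simulate_null_delta(20, 25, cfg),
                          simulate_null_delta(20, 25, cfg))


def test_band_narrows_with_depth_and_nests_with_level():
    cfg95 = NullConfig(n_reps=4000, seed=3, depth_grid=[(5, 5), (25, 25)])
    band95 = ci_band(cfg95)
    lo5, hi5 = band95.bounds[(5, 5)]
    lo25, hi25 = band95.bounds[(25, 25)]
    assert hi25 < hi5 and lo25 > lo5
    assert lo5 <= 0.0 <= hi5
    band99 = ci_band(NullConfig(n_reps=4000, seed=3, level=0.99,
                                depth_grid=[(5, 5), (25, 25)]))
    lo99, hi99 = band99.bounds[(25, 25)]
    assert lo99 <= lo25 and hi99 >= hi25


def test_band_bitwise_reproducible():
    cfg = NullConfig(n_reps=1000, seed=8, depth_grid=[(10, 12), (24, 24)])
    assert ci_band(cfg).bounds == ci_band(cfg).bounds


def test_band_lookup_nearest_pair():
    band = CiBand(level=0.95, bounds={(10, 10): (-0.5, 0.5), (30, 30): (-0.2, 0.2)})
    assert band.lookup(12, 11) == (-0.5, 0.5)
    assert band.lookup(28, 33) == (-0.2, 0.2)


def test_call_regions_runs_and_merging():
    band = CiBand(level=0.95, bounds={(24, 24): (-0.3, 0.3)})
    deltas = [0.0, 0.4, 0.5, 0.6, 0.0, 0.5, 0.5, 0.0, 0.9]
    windows = [make_window(i, d) for i, d in enumerate(deltas)]
    regions = call_regions(windows, band, min_run=3)
    # only the first run reaches 3 consecutive windows; overlapping windows merge
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (windows[1].start, windows[3].end)
    assert r.n_windows == 3
    assert r.peak_delta == pytest.approx(0.6)


def test_call_regions_sides_missing_and_empty():
    band = CiBand(level=0.95, bounds={(24, 24): (-0.3, 0.3)})
    windows = [make_window(i, -0.5) for i in range(4)]
    assert call_regions(windows, band, min_run=3) == []
    lower = call_regions(windows, band, min_run=3, side="lower")
    assert len(lower) == 1 and lower[0].n_windows == 4
    # missing windows break runs
    broken = [make_window(0, 0.5), make_window(1, 0.5),
              make_window(2, 0.5, missing=True), make_window(3, 0.5)]
    assert call_regions(broken, band, min_run=3) == []
    assert call_regions([], band) == []


def test_no_regions_on_null_genome():
    """With no QTL (phenotype independent of genotype) the caller stays quiet."""
    from lesrmap import simulate as sim
    from lesrmap import snp_index as si
    from lesrmap import window_scan as ws

    zero = 0
    n_runs = 10
    for seed in range(n_runs):
        cfg = sim.SimConfig(seed=seed, n_f2=400, bulk_size=20, n_sites=300,
                            chrom_lengths={"c": 10_000_000}, qtl_chrom="c",
                            qtl_pos=5_000_000, low_mean=42.68, low_sd=3.39)
        out = sim.simulate_experiment(cfg)
        recs = si.compute_index_records(si.filter_snps(out.observations))
        windows = ws.sliding_windows(recs, chrom_lengths=cfg.chrom_lengths)
        band = ci_band(NullConfig(bulk_size=20, seed=seed, depth_grid=40))
        zero += not call_regions(windows, band)
    assert zero >= 0.9 * n_runs


def test_planted_qtl_recovered(small_sim_config):
    from lesrmap import simulate as sim
    from lesrmap import snp_index as si
    from lesrmap import window_scan as ws

    out = sim.simulate_experiment(small_sim_config)
    recs = si.compute_index_records(si.filter_snps(out.observations))
    windows = ws.sliding_windows(recs, chrom_lengths=small_sim_config.chrom_lengths)
    band = ci_band(NullConfig(bulk_size=small_sim_config.bulk_size,
                              seed=small_sim_config.seed, depth_grid=40))
    regions = call_regions(windows, band)
    assert regions
    qtl = small_sim_config.qtl_pos
    assert any(r.start <= qtl <= r.end for r in regions)


def _containment_rate(depth, bulk, seeds):
    from lesrmap import simulate as sim
    from lesrmap import snp_index as si
    from lesrmap import window_scan as ws

    hits = 0
    for seed in seeds:
        cfg = sim.SimConfig(seed=seed, n_f2=600, bulk_size=bulk, n_sites=500,
                            mean_depth=depth, chrom_lengths={"c": 10_000_000},
                            qtl_chrom="c", qtl_pos=6_000_000)
        out = sim.simulate_experiment(cfg)
        recs = si.compute_index_records(si.filter_snps(out.observations))
        windows = ws.sliding_windows(recs, chrom_lengths=cfg.chrom_lengths)
        band = ci_band(NullConfig(bulk_size=bulk, seed=seed, depth_grid=40))
        regions = call_regions(windows, band)
        hits += any(r.start <= cfg.qtl_pos <= r.end for r in regions)
    return hits / len(seeds)


def test_recovery_power_monotone_in_depth_and_bulk():
    """Detection power does not fall as depth or bulk size grows (weak form:
    the largest grid point is at least as good as the smallest)."""
    seeds = range(4)
    by_depth = [_containment_rate(d, 20, seeds) for d in (8, 16, 24)]
    assert by_depth[-1] >= by_depth[0]
    by_bulk = [_containment_rate(24, b, seeds) for b in (10, 20, 30)]
    assert by_bulk[-1] >= by_bulk[0]


def test_config_validation():
    with pytest.raises(ValueError):
        NullConfig(bulk_size=0)
    with pytest.raises(ValueError):
        NullConfig(n_reps=10)
    with pytest.raises(ValueError):
        NullConfig(level=1.2)
    with pytest.raises(ValueError):
        simulate_null_delta(0, 10, NullConfig())
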