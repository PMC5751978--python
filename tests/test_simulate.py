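"""Mendelian and recombination structure of the synthetic F2 generator."""
import json

import numpy as np
import pytest
from scipy.stats import chisquare

from lesrmap import simulate as sim
from lesrmap.phenotype import classify_plant, compute_exertion_rates, load_phenotypes
from lesrmap.snp_index import load_pool_variants


def test_config_validation():
    with pytest.raises(ValueError):
        sim.SimConfig(chrom_lengths={})
    with pytest.raises(ValueError):
        sim.SimConfig(qtl_chrom="nope")
    with pytest.raises(ValueError):
        sim.SimConfig(qtl_pos=10**9)
    with pytest.raises(ValueError):
        sim.SimConfig(n_f2=40, bulk_size=30)


def test_mendelian_genotype_frequencies():
    truth = sim.simulate_f2(sim.SimConfig(seed=0, n_sites=20))
    counts = np.bincount(truth.qtl_dosage, minlength=3)
    assert chisquare(counts, [500, 1000, 500]).pvalue > 0.001
    # same check at an arbitrary segregating site
    site = truth.site_dosage["chr10"][:, 7]
    assert chisquare(np.bincount(site, minlength=3), [500, 1000, 500]).pvalue > 0.001


def test_haldane_recombinant_fraction_10cm():
    rng = np.random.default_rng(2)
    gametes = sim.simulate_gametes(
        20_000_000, 20_000, np.array([5_000_000, 9_000_000]), 400_000, rng)
    rf = float(np.mean(gametes[:, 0] != gametes[:, 1]))
    expected = (1 - np.exp(-0.2)) / 2  # Haldane at 10 cM
    assert rf == pytest.approx(expected, abs=0.01)


def test_phenotypes_track_genotype_classes():
    truth = sim.assign_phenotypes(sim.simulate_f2(sim.SimConfig(seed=1, n_sites=10)))
    aa = truth.qtl_dosage == 2
    low_frac = np.mean([classify_plant(x) == "low" for x in truth.se])
    assert 0.21 <= low_frac <= 0.29  # binomial(2000, 1/4) range
    # classes separate: every aa plant below the boundary, others above
    assert truth.se[aa].max() < 25.0 < truth.se[~aa].min()


def test_zero_variance_phenotypes_hit_class_means():
    cfg = sim.SimConfig(seed=2, n_sites=10, low_sd=0.0, high_sd=0.0)
    truth = sim.assign_phenotypes(sim.simulate_f2(cfg))
    aa = truth.qtl_dosage == 2
    assert np.all(truth.se[aa] == cfg.low_mean)
    assert np.all(truth.se[~aa] == cfg.high_mean)


def test_pure_bulks_and_qtl_site_index(small_sim_config):
    """With no sequencing error the low bulk is fixed for the mutant allele."""
    import dataclasses

    cfg = dataclasses.replace(small_sim_config, seq_error=0.0)
    out = sim.simulate_experiment(cfg)
    truth = out.truth
    assert len(truth.bulk_low) == cfg.bulk_size == len(truth.bulk_high)
    assert np.all(truth.qtl_dosage[truth.bulk_low] == 2)
    # index at the site nearest the QTL
    pos = truth.site_positions[cfg.qtl_chrom]
    near = int(np.argmin(np.abs(pos - cfg.qtl_pos)))
    freq_low = truth.site_dosage[cfg.qtl_chrom][truth.bulk_low, near].mean() / 2
    obs = [o for o in out.observations if o.pos == pos[near]][0]
    if freq_low == 1.0 and obs.depth_l > 0:
        assert obs.alt_l == obs.depth_l  # L-pool index exactly 1


def test_unlinked_chromosome_delta_near_zero():
    """Sites on a chromosome without the QTL average to delta ~ 0.

    A single run's chromosome-mean delta carries the shared bulk-mosaic
    noise of the 30-plant bulks (sd ~ 0.08), so the unlinked-null
    expectation is asserted on the across-seed average.
    """
    from lesrmap.snp_index import compute_index_records, filter_snps

    means = []
    for seed in range(8):
        cfg = sim.SimConfig(
            chrom_lengths={"chr10": 10_000_000, "chr02": 10_000_000},
            qtl_chrom="chr10", qtl_pos=5_000_000, n_sites=600,
            n_f2=800, seed=seed)
        out = sim.simulate_experiment(cfg)
        recs = compute_index_records(filter_snps(out.observations))
        means.append(np.mean([r.delta for r in recs if r.chrom == "chr02"]))
    assert abs(float(np.mean(means))) <= 0.05


def test_determinism_under_seed(small_sim_config):
    a = sim.simulate_experiment(small_sim_config)
    b = sim.simulate_experiment(small_sim_config)
    assert a.observations == b.observations
    assert a.phenotypes.equals(b.phenotypes)
    assert np.array_equal(a.truth.qtl_dosage, b.truth.qtl_dosage)


def test_emitted_files_round_trip(tmp_path, small_sim_config):
    out = sim.simulate_experiment(small_sim_config)
    paths = sim.write_outputs(out, tmp_path)

    loaded = load_pool_variants(paths["pool_table"])
    assert loaded == out.observations

    pheno = load_phenotypes(paths["phenotypes"])
    assert len(pheno) == small_sim_config.n_f2
    # recomputed SE from quantised counts stays within half a point of truth
    se = np.array([compute_exertion_rates(c).se for c in pheno])
    assert np.max(np.abs(se - out.truth.se)) < 0.5

    from lesrmap.finemap import load_genotype_matrix, load_marker_panel

    panel = load_marker_panel(paths["marker_panel"])
    plants = load_genotype_matrix(paths["genotype_matrix"], panel)
    assert len(plants) == int((out.truth.qtl_dosage == 2).sum())
    assert all(p.phenotype == "low" for p in plants)

    truth_doc = json.loads((tmp_path / "truth.json").read_text())
    assert truth_doc["qtl"]["pos"] == small_sim_config.qtl_pos
    assert truth_doc["bulk_low"] == out.truth.bulk_low.tolist()


def test_minimal_vcf_round_trip(tmp_path, small_sim_config):
    from lesrmap.snp_index import load_vcf

    out = sim.simulate_experiment(small_sim_config)
    vcf_path = tmp_path / "pools.vcf"
    sim.write_vcf(out, vcf_path)
    loaded = load_vcf(vcf_path, "H", "L", mutant_parent="P_MUT", wild_parent="P_WT")
    assert [(o.chrom, o.pos, o.alt_h, o.alt_l) for o in loaded] == [
        (o.chrom, o.pos, o.alt_h, o.alt_l) for o in out.observations]


def test_recessive_panel_codes_match_dosage(small_sim_config):
    out = sim.simulate_experiment(small_sim_config)
    truth = out.truth
    recessive = np.flatnonzero(truth.qtl_dosage == 2)
    code = {2: "A", 1: "H", 0: "B"}
    gm = out.genotype_matrix.set_index("plant_id")
    for j, p in enumerate(truth.marker_positions):
        col = gm[f"SM-{j + 1}"]
        for i in recessive[:10]:
            assert col[f"F2-{i:04d}"] == code[int(truth.marker_dosage[i, j])]
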