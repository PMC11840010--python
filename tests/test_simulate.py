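"""Synthetic experiment generator: determinism, labelling model, images,
tracer mass balance."""

import numpy as np
import pandas as pd
import pytest

from cryosip import (SimulationConfig, cell_rate_table, classify_active,
                     render_sims_images, roi_quantify, simulate_experiment,
                     write_experiment)


class TestDeterminism:
    def test_same_seed_same_tables(self):
        a = simulate_experiment(SimulationConfig(seed=21))
        b = simulate_experiment(SimulationConfig(seed=21))
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.bulk, b.bulk)
        pd.testing.assert_frame_equal(a.pools, b.pools)
        pd.testing.assert_frame_equal(a.eds, b.eds)

    def test_different_seed_differs(self):
        a = simulate_experiment(SimulationConfig(seed=21))
        b = simulate_experiment(SimulationConfig(seed=22))
        assert not np.allclose(a.cells.frac13c, b.cells.frac13c)

    def test_written_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=8, n_cells=24)
        p1 = write_experiment(simulate_experiment(cfg), tmp_path / "a",
                              images=True)
        p2 = write_experiment(simulate_experiment(cfg), tmp_path / "b",
                              images=True)
        assert p1.keys() == p2.keys()
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestLabellingModel:
    def test_noise_free_single_cell_recovers_mu_exactly(self):
        cfg = SimulationConfig(seed=2, n_cells=1, inactive_fraction=0.0,
                               noise_free=True, dic_excess_half_life_h=None,
                               cell_groups=(("control", "T2"),))
        sim = simulate_experiment(cfg)
        rates = cell_rate_table(sim.cells, sim.pools)
        mu_true = sim.truth.cells.mu_true_per_day.iloc[0]
        assert rates.c_growth_d.iloc[0] == pytest.approx(mu_true, rel=1e-12)

    def test_all_inactive_population_is_unlabelled(self):
        cfg = SimulationConfig(seed=4, inactive_fraction=1.0)
        sim = simulate_experiment(cfg)
        assert (sim.truth.cells.mu_true_per_day == 0).all()
        # cell label stays within natural-abundance scatter
        assert sim.cells.frac13c.max() < 0.0111 + 6 * 0.00016
        # bulk labelling reduces to the non-algal background
        t2 = sim.bulk[(sim.bulk.treatment == "control")
                      & (sim.bulk.timepoint == "T2")]
        f_bg = 1 - 2.0 ** (-cfg.background_growth * 1.25)
        e_pool = sim.truth.pools.query(
            "treatment=='control' and substrate=='DIC' and timepoint=='T2'"
        )["excess_flux_avg"].iloc[0]
        expected = (1 - sim.truth.summary["algal_fraction_poc"]) * f_bg * e_pool
        observed = t2.ap13c_poc.mean() - 1.11
        assert observed == pytest.approx(expected, abs=0.1)

    def test_activity_classification_recovers_inactive_fraction(self):
        cfg = SimulationConfig(seed=6)
        sim = simulate_experiment(cfg)
        active, _ = classify_active(sim.cells.frac13c.to_numpy() * 100.0)
        inactive_frac = 1.0 - active.mean()
        # binomial 95% CI around the configured fraction at n = 244
        ci = 1.96 * np.sqrt(0.1 * 0.9 / cfg.n_cells)
        assert abs(inactive_frac - cfg.inactive_fraction) < ci

    def test_growth_defaults_target_field_population(self):
        # active-population mean ~0.47/d, SD ~0.24/d under the defaults
        mus = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, cell_groups=(("control", "T2"),))
            t = simulate_experiment(cfg).truth.cells
            mus.append(t[t.active_true].mu_true_per_day)
        mus = np.concatenate(mus)
        assert mus.mean() == pytest.approx(0.47, abs=0.02)
        assert mus.std(ddof=1) == pytest.approx(0.24, abs=0.03)

    def test_geometry_defaults_target_observed_biovolume(self):
        sim = simulate_experiment(SimulationConfig(seed=9, n_cells=2000))
        bv = sim.truth.cells.biovolume_um3
        assert bv.mean() == pytest.approx(1414, rel=0.1)
        assert bv.std(ddof=1) == pytest.approx(873, rel=0.25)

    def test_infeasible_community_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_experiment(SimulationConfig(seed=0, poc_t0_umol_l=10.0))


class TestPoolKinetics:
    def test_pool_excess_declines_with_half_life(self):
        sim = simulate_experiment(SimulationConfig(seed=1))
        dic = sim.truth.pools.query(
            "treatment=='control' and substrate=='DIC'").set_index("timepoint")
        assert dic.loc["T1", "excess"] > dic.loc["T2", "excess"]
        # defaults emulate the observed ~4.4 -> ~3.6 decline
        assert dic.loc["T1", "excess"] == pytest.approx(4.3, abs=0.2)
        assert dic.loc["T2", "excess"] == pytest.approx(3.6, abs=0.2)

    def test_n_tracer_concentration_depletion(self):
        sim = simulate_experiment(SimulationConfig(seed=1))
        nh4 = sim.truth.pools.query(
            "treatment=='NH4' and substrate=='NH4'").set_index("timepoint")
        no3 = sim.truth.pools.query(
            "treatment=='NO3' and substrate=='NO3'").set_index("timepoint")
        # <3% of NH4+ and <37% of NO3- left after the first sampling
        assert nh4.loc["T1", "concentration_um"] < 0.03 * 10.078
        assert no3.loc["T1", "concentration_um"] < 0.37 * 10.05

    def test_tracer_mass_balance_in_uptake_mode(self):
        # small, slow community against large pools: atoms must balance
        cfg = SimulationConfig(
            seed=3, noise_free=True, depletion_mode="uptake",
            n_cells=50, cell_groups=(("control", "T2"),),
            poc_t0_umol_l=100.0, poc_t0_sd=0.0, abundance_per_ml=500.0,
            background_growth=0.2, ambient_dic_um=2000.0,
            ambient_nh4_um=50.0, ambient_no3_um=50.0)
        sim = simulate_experiment(cfg)
        mb = sim.truth.mass_balance
        assert not mb.empty
        total = mb.pool_tracer_umol_l + mb.biomass_tracer_umol_l
        assert np.allclose(total, mb.initial_tracer_umol_l, rtol=1e-9)
        # biomass term re-derivable from the per-cell ground truth
        row = mb.query("treatment=='control' and substrate=='DIC' "
                       "and timepoint=='T2'").iloc[0]
        truth = sim.truth.cells
        f_alg = np.mean(1 - 2.0 ** (-truth.mu_true_per_day * 1.25))
        f_bg = 1 - 2.0 ** (-cfg.background_growth * 1.25)
        alg = sim.truth.summary["algal_fraction_poc"]
        e0 = sim.truth.pools.query(
            "treatment=='control' and substrate=='DIC'")["excess0"].iloc[0]
        expected = cfg.poc_t0_umol_l * (alg * f_alg + (1 - alg) * f_bg) \
            * e0 / 100.0
        assert row.biomass_tracer_umol_l == pytest.approx(expected, rel=1e-9)

    def test_uptake_mode_exhaustion_is_an_error(self):
        cfg = SimulationConfig(seed=3, depletion_mode="uptake",
                               ambient_dic_um=100.0)
        with pytest.raises(ValueError, match="exhausts"):
            simulate_experiment(cfg)


class TestImageRendering:
    def test_zero_background_outside_masks(self):
        cfg = SimulationConfig(seed=7, n_cells=6,
                               cell_groups=(("control", "T2"),))
        sim = simulate_experiment(cfg)
        fields = render_sims_images(sim.truth.cells, cfg)
        for fld in fields:
            outside = fld["labels"] == 0
            for arr in fld["images"].values():
                assert arr[outside].sum() == 0

    def test_noise_free_roi_fraction_equals_truth(self):
        cfg = SimulationConfig(seed=7, n_cells=4, noise_free=True,
                               cell_groups=(("control", "T2"),))
        sim = simulate_experiment(cfg)
        fields = render_sims_images(sim.truth.cells, cfg)
        roi = pd.concat([roi_quantify(f["images"], f["labels"])
                         for f in fields])
        merged = roi.merge(sim.truth.cells, on="cell_id")
        assert np.allclose(merged.frac13c, merged.frac13c_true, rtol=1e-12)
        assert np.allclose(merged.frac15n, merged.frac15n_true, rtol=1e-12)

    def test_poisson_roi_fraction_converges_at_high_counts(self):
        cfg = SimulationConfig(seed=13, n_cells=8, counts_per_cell=1e6,
                               cell_groups=(("control", "T2"),))
        sim = simulate_experiment(cfg)
        fields = render_sims_images(sim.truth.cells, cfg)
        roi = pd.concat([roi_quantify(f["images"], f["labels"])
                         for f in fields])
        merged = roi.merge(sim.truth.cells, on="cell_id")
        err = np.abs(merged.frac13c - merged.frac13c_true)
        assert (err < 1e-3).all()  # within 0.1 atom% at 1e6 counts

    def test_total_counts_match_poisson_expectation(self):
        cfg = SimulationConfig(seed=17, n_cells=12,
                               cell_groups=(("control", "T2"),))
        sim = simulate_experiment(cfg)
        fields = render_sims_images(sim.truth.cells, cfg)
        total = sum(f["images"]["12C14N"].sum() for f in fields)
        expected = cfg.n_cells * cfg.counts_per_cell
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_oversized_cell_rejected(self):
        cfg = SimulationConfig(seed=1, n_cells=1, raster_size=32,
                               cell_groups=(("control", "T2"),))
        sim = simulate_experiment(cfg)
        big = sim.truth.cells.assign(length_um=100.0, width_um=50.0)
        with pytest.raises(ValueError, match="does not fit"):
            render_sims_images(big, cfg)

    def test_labels_are_cell_ids(self, default_sim):
        fields = render_sims_images(default_sim.truth.cells.head(10),
                                    default_sim.config)
        seen = np.unique(np.concatenate(
            [np.unique(f["labels"]) for f in fields]))
        assert set(seen[seen > 0]) == set(
            default_sim.truth.cells.head(10).cell_id)


class TestEndToEndRecovery:
    def test_contribution_recovered_across_replicates(self):
        # simulate -> rates -> contribution, averaged over replicate
        # seeds, must sit on the true algal share within 3 MC-SE
        from cryosip import (AbundanceEstimate, bulk_rate_table,
                             contribution_table, population_summary)
        diffs = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, n_cells=60,
                                   inactive_fraction=0.0,
                                   cell_groups=(("control", "T2"),))
            sim = simulate_experiment(cfg)
            rates = cell_rate_table(sim.cells, sim.pools)
            summary = population_summary(rates, active_only=False)
            bulk_rates = bulk_rate_table(sim.bulk, sim.pools)
            est = AbundanceEstimate(cfg.abundance_per_ml, 0.0, 1.0)
            table = contribution_table(summary, bulk_rates, est)
            got = table.query(
                "substrate=='DIC' and timepoint=='T2'")["percent"].iloc[0]
            want = sim.truth.contribution.query(
                "treatment=='control' and substrate=='DIC' "
                "and timepoint=='T2'")["true_percent"].iloc[0]
            diffs.append(got - want)
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * mc_se
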