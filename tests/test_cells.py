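"""ROI quantification, cell composition chain, per-cell rates, EDS ratios."""

import numpy as np
import pandas as pd
import pytest

from cryosip import (assimilation_cn_ratio, biovolume_cylinder,
                     cell_dry_weight, cell_elemental_content,
                     cell_fixation_rate, cell_growth_rate, cell_rate_table,
                     population_summary, roi_quantify, stoichiometry_from_eds)
from cryosip.constants import ATOMIC_MASS, MASS_FRACTIONS


def _uniform_images(shape, c12, c13, c15):
    return {"12C14N": np.full(shape, float(c12)),
            "13C14N": np.full(shape, float(c13)),
            "12C15N": np.full(shape, float(c15))}


class TestRoiQuantify:
    def test_uniform_counts_give_exact_fraction(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:6, 2:6] = 1
        out = roi_quantify(_uniform_images((8, 8), 99, 1, 0), labels)
        assert len(out) == 1
        assert out.frac13c.iloc[0] == pytest.approx(0.01)
        assert out.frac15n.iloc[0] == 0.0
        assert out.roi_pixels.iloc[0] == 16

    def test_empty_mask_gives_empty_output(self):
        labels = np.zeros((4, 4), dtype=int)
        out = roi_quantify(_uniform_images((4, 4), 1, 0, 0), labels)
        assert out.empty

    def test_poisson_fraction_within_counting_error(self):
        rng = np.random.default_rng(3)
        true_frac, n_px = 0.05, 400
        lam12 = 25000.0 / n_px  # >= 1e4 total counts in the ROI
        lam13 = lam12 * true_frac / (1 - true_frac)
        labels = np.zeros((20, 20), dtype=int)
        labels[:] = 1
        images = {"12C14N": rng.poisson(lam12, (20, 20)).astype(float),
                  "13C14N": rng.poisson(lam13, (20, 20)).astype(float),
                  "12C15N": np.zeros((20, 20))}
        out = roi_quantify(images, labels)
        total = images["12C14N"].sum() + images["13C14N"].sum()
        se = np.sqrt(true_frac * (1 - true_frac) / total)
        assert abs(out.frac13c.iloc[0] - true_frac) < 3 * se

    def test_zero_denominator_pixels_excluded(self):
        labels = np.ones((2, 2), dtype=int)
        images = _uniform_images((2, 2), 90, 10, 0)
        images["12C14N"][0, 0] = 0.0
        images["13C14N"][0, 0] = 0.0
        out = roi_quantify(images, labels)
        assert out.frac13c.iloc[0] == pytest.approx(0.1)

    def test_all_zero_roi_skipped_with_warning(self):
        labels = np.ones((2, 2), dtype=int)
        with pytest.warns(UserWarning, match="skipped"):
            out = roi_quantify(_uniform_images((2, 2), 0, 0, 0), labels)
        assert out.empty

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            roi_quantify(_uniform_images((3, 3), 1, 1, 1),
                         np.ones((4, 4), dtype=int))

    def test_count_sum_estimator_matches_on_uniform_images(self):
        labels = np.ones((5, 5), dtype=int)
        images = _uniform_images((5, 5), 99, 1, 0)
        a = roi_quantify(images, labels, estimator="pixel_mean")
        b = roi_quantify(images, labels, estimator="count_sum")
        assert a.frac13c.iloc[0] == pytest.approx(b.frac13c.iloc[0])


class TestCompositionChain:
    def test_cylinder_volume(self):
        assert biovolume_cylinder(1.0, 2.0) == pytest.approx(np.pi)
        # mean observed cell: 16.0 x 10.6 µm -> ~1412 µm^3
        assert biovolume_cylinder(16.0, 10.6) == pytest.approx(1412, abs=1)

    def test_width_scaling_law(self):
        assert biovolume_cylinder(3.0, 4.0) == pytest.approx(
            4 * biovolume_cylinder(3.0, 2.0))

    def test_dry_weight(self):
        assert cell_dry_weight(1414.0) == pytest.approx(459.3, abs=0.1)
        assert cell_dry_weight(0.0) == 0.0
        # at density 1000 and dry fraction 1 the pg value equals the µm^3
        assert cell_dry_weight(123.0, 1000.0, 1.0) == pytest.approx(123.0)

    def test_elemental_content(self):
        comp = cell_elemental_content(459.3)
        assert comp.content_c_pmol == pytest.approx(459.3 * 0.72 / 12.011)
        assert comp.content_c_pmol == pytest.approx(27.5, abs=0.1)
        assert comp.content_n_pmol == pytest.approx(1.31, abs=0.01)
        zero = cell_elemental_content(0.0)
        assert (zero.content_c_pmol, zero.content_n_pmol,
                zero.content_p_pmol) == (0.0, 0.0, 0.0)

    def test_chain_is_linear_in_biovolume(self):
        one = cell_elemental_content(cell_dry_weight(700.0))
        two = cell_elemental_content(cell_dry_weight(1400.0))
        assert two.content_c_pmol == pytest.approx(2 * one.content_c_pmol)
        assert two.content_p_pmol == pytest.approx(2 * one.content_p_pmol)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            biovolume_cylinder(0.0, 1.0)


class TestCellRates:
    def test_unlabelled_cell_fixes_nothing(self):
        assert cell_fixation_rate(0.0, 3.9, 27.5, 1.25) == 0.0

    def test_fully_labelled_cell_turns_over_its_quota(self):
        assert cell_fixation_rate(3.9, 3.9, 27.5, 1.25) == pytest.approx(22.0)

    def test_fixation_inversion_oracle(self):
        # target the observed per-cell magnitude: mu=0.27/d over 1.25 d
        mu, dt, content, e_pool = 0.27, 1.25, 27.5, 3.9
        f = 1.0 - 2.0 ** (-mu * dt)
        rate = cell_fixation_rate(f * e_pool, e_pool, content, dt)
        assert rate == pytest.approx(f * content / dt)
        assert rate == pytest.approx(4.6, abs=0.05)

    def test_growth_consistency_with_fixation(self):
        # fixation*dt/content == 1 - 2^(-mu*dt) exactly (noise-free)
        for mu in (0.05, 0.47, 1.3):
            dt, e_pool, content = 1.25, 3.9, 27.5
            f = 1.0 - 2.0 ** (-mu * dt)
            rate = cell_fixation_rate(f * e_pool, e_pool, content, dt)
            mu_back = cell_growth_rate(e_pool, f * e_pool, dt)
            assert rate * dt / content == pytest.approx(
                1.0 - 2.0 ** (-mu_back * dt), rel=1e-12)
            assert mu_back == pytest.approx(mu, rel=1e-12)

    def test_cn_assimilation_ratio(self):
        ratios, summary = assimilation_cn_ratio([9.7], [0.183])
        assert ratios[0] == pytest.approx(53.0, abs=0.1)
        assert summary["n"] == 1
        ratios, _ = assimilation_cn_ratio([2.0, 4.0], [2.0, 4.0])
        assert np.allclose(ratios, 1.0)

    def test_cn_ratio_scale_invariant(self):
        a, _ = assimilation_cn_ratio([1.0, 2.0], [0.1, 0.3])
        b, _ = assimilation_cn_ratio([10.0, 20.0], [1.0, 3.0])
        assert np.allclose(a, b)

    def test_cn_ratio_excludes_nonpositive_n(self):
        with pytest.warns(UserWarning, match="excluded"):
            ratios, summary = assimilation_cn_ratio([1.0, 1.0], [0.0, 0.5])
        assert summary["n"] == 1
        assert ratios[0] == pytest.approx(2.0)


class TestStoichiometry:
    @staticmethod
    def _eds(c, n, p):
        return pd.DataFrame({"cell_id": np.arange(len(c)),
                             "atom_percent_c": c, "atom_percent_n": n,
                             "atom_percent_p": p})

    def test_constructed_ratios(self):
        per_cell, summary = stoichiometry_from_eds(self._eds([66], [10], [0.5]))
        assert per_cell.cn.iloc[0] == pytest.approx(6.6)
        assert per_cell.np.iloc[0] == pytest.approx(20.0)

    def test_redfield_cells_recover_redfield_exactly(self):
        # atom% in exact Redfield proportions C:N:P = 6.6 : 1 (x16) : ...
        c, n, p = 116.0 / 2, 116.0 / 6.6 / 2, 1.0 / 2
        per_cell, summary = stoichiometry_from_eds(
            self._eds([c] * 3, [n] * 3, [p] * 3))
        row = summary.set_index("ratio")
        assert row.loc["C:P", "mean"] == pytest.approx(116.0)
        assert row.loc["C:N", "mean"] == pytest.approx(6.6)
        assert row.loc["C:N", "mean"] == pytest.approx(
            row.loc["C:N", "redfield"])

    def test_mass_fraction_derived_atomic_cn(self):
        # the dry-mass fractions imply atomic C:N ~21 and C:P ~46
        cn = (MASS_FRACTIONS["C"] / ATOMIC_MASS["C"]) \
            / (MASS_FRACTIONS["N"] / ATOMIC_MASS["N"])
        cp = (MASS_FRACTIONS["C"] / ATOMIC_MASS["C"]) \
            / (MASS_FRACTIONS["P"] / ATOMIC_MASS["P"])
        assert cn == pytest.approx(21.0, abs=0.05)
        assert cp == pytest.approx(46.4, abs=0.1)

    def test_single_cell_has_no_sd(self):
        _, summary = stoichiometry_from_eds(self._eds([66], [10], [0.5]))
        assert summary["sd"].isna().all()
        assert (summary["n"] == 1).all()

    def test_zero_denominator_cells_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            per_cell, _ = stoichiometry_from_eds(
                self._eds([66, 50], [10, 0.0], [0.5, 0.5]))
        assert len(per_cell) == 1

    def test_simulated_eds_recovers_target_ratios(self, default_sim):
        _, summary = stoichiometry_from_eds(default_sim.eds)
        row = summary.set_index("ratio")
        cfg = default_sim.config
        assert row.loc["C:N", "mean"] == pytest.approx(
            cfg.eds_cn_mean, rel=0.15)
        assert row.loc["N:P", "mean"] == pytest.approx(
            cfg.eds_np_mean, rel=0.15)


class TestPopulationSummary:
    @staticmethod
    def _rates(n, n_inactive):
        active = np.ones(n, dtype=bool)
        active[:n_inactive] = False
        return pd.DataFrame({
            "treatment": "control", "timepoint": "T2", "active": active,
            "c_fix_pmol_d": np.linspace(1, 5, n),
            "c_growth_d": np.linspace(0.1, 0.9, n),
        })

    def test_active_only_excludes_inactive_cells(self):
        summary = population_summary(self._rates(244, 24), active_only=True)
        assert (summary["n"] == 220).all()

    def test_all_active_summaries_identical(self):
        df = self._rates(10, 0)
        a = population_summary(df, active_only=True)
        b = population_summary(df, active_only=False)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_active_set_warns(self):
        with pytest.warns(UserWarning, match="no active"):
            out = population_summary(self._rates(5, 5), active_only=True)
        assert out.empty


class TestCellRateTable:
    def test_population_mean_quota_is_default(self, noise_free_sim):
        rates = cell_rate_table(noise_free_sim.cells, noise_free_sim.pools)
        assert (rates["content_source"] == "population_mean").all()
        assert rates["content_c_pmol"].nunique() == 1

    def test_noise_free_growth_matches_truth_exactly(self, noise_free_sim):
        rates = cell_rate_table(noise_free_sim.cells, noise_free_sim.pools)
        truth = noise_free_sim.truth.cells
        merged = rates.merge(
            truth[["cell_id", "mu_true_per_day", "active_true"]], on="cell_id")
        act = merged[merged.active_true & (merged.mu_true_per_day > 0)]
        assert np.allclose(act.c_growth_d, act.mu_true_per_day, rtol=1e-9)

    def test_per_cell_quota_option(self, noise_free_sim):
        rates = cell_rate_table(noise_free_sim.cells, noise_free_sim.pools,
                                content_basis="per_cell")
        assert rates["content_c_pmol"].nunique() > 1
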