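import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import facespace as fs


@pytest.fixture(scope="module")
def reference(default_grid):
    design12 = fs.build_rsa_predictors(default_grid, viewpoints=False)
    rdm12 = fs.euclidean_rdm(default_grid.coords_2d,
                             labels=default_grid.face_labels)
    return default_grid, design12, rdm12


class TestPredictors:
    def test_partition_is_complete(self, reference):
        grid, design, rdm = reference
        sq = rdm.vector ** 2
        ecc = design.matrix[:, 0]
        direction = design.matrix[:, 1]
        assert np.allclose(ecc + direction, sq, atol=1e-12)

    def test_same_eccentricity_pair_entries(self, reference):
        """60-degree pair at eccentricity e: ecc 0, dir 2 e^2 (1 - cos 60)."""
        grid, design, _ = reference
        ecc_l = grid.ecc_levels
        ang = grid.angles_deg
        i, j = np.triu_indices(12, k=1)
        sel = (ecc_l[i] == ecc_l[j]) & (np.abs(ang[i] - ang[j]) == 60.0)
        e = ecc_l[i][sel]
        assert np.allclose(design.matrix[sel, 0], 0.0, atol=1e-12)
        assert np.allclose(design.matrix[sel, 1], 2 * e**2 * (1 - 0.5), atol=1e-12)

    def test_same_direction_pair_entries(self, reference):
        grid, design, _ = reference
        ecc_l = grid.ecc_levels
        ang = grid.angles_deg
        i, j = np.triu_indices(12, k=1)
        sel = (ang[i] == ang[j]) & (ecc_l[i] == 0.3) & (ecc_l[j] == 1.0)
        sel |= (ang[i] == ang[j]) & (ecc_l[j] == 0.3) & (ecc_l[i] == 1.0)
        assert np.allclose(design.matrix[sel, 0], 0.7**2, atol=1e-12)
        assert np.allclose(design.matrix[sel, 1], 0.0, atol=1e-12)

    def test_viewpoint_masks_partition_all_pairs(self, default_grid):
        design = fs.build_rsa_predictors(default_grid, viewpoints=True)
        within_const = design.matrix[:, 2]
        across_const = design.matrix[:, 5]
        assert np.allclose(within_const + across_const, 1.0)
        assert design.matrix.shape == (276, 6)


class TestRegression:
    def test_self_check_returns_one_one_zero(self, reference):
        """Regressing the squared reference matrix on its own partition."""
        _, design, rdm = reference
        fit = fs.fit_rsa_regression(rdm, design)
        assert np.allclose(
            fit.estimates_squared.to_numpy(), [1.0, 1.0, 0.0], atol=1e-10
        )
        assert np.allclose(fit.estimates.to_numpy(), [1.0, 1.0, 0.0], atol=1e-6)
        assert np.abs(fit.residuals).max() < 1e-10

    def test_scaled_data_scales_through_back_transform(self, reference):
        _, design, rdm = reference
        doubled = fs.RDM(labels=rdm.labels,
                         matrix=np.sqrt(2.0) * rdm.matrix)  # 2x squared distances
        fit = fs.fit_rsa_regression(doubled, design)
        assert fit.estimates["eccentricity"] == pytest.approx(np.sqrt(2), abs=1e-8)
        assert fit.estimates["direction"] == pytest.approx(np.sqrt(2), abs=1e-8)

    def test_signed_transform_roundtrip_with_negative_distances(self, reference):
        _, design, rdm = reference
        rng = np.random.default_rng(0)
        noisy = rdm.vector + rng.normal(0, 0.3, size=66)
        noisy[:5] = -np.abs(noisy[:5])  # cross-validated estimates can dip below 0
        data = fs.RDM.from_vector(noisy, rdm.labels, metric="crossvalidated")
        fit = fs.fit_rsa_regression(data, design)
        y = np.sign(noisy) * noisy**2
        beta, *_ = np.linalg.lstsq(design.matrix, y, rcond=None)
        assert np.allclose(
            fit.estimates.to_numpy(), np.sign(beta) * np.sqrt(np.abs(beta)),
            atol=1e-12,
        )
        assert np.allclose(fit.fitted + fit.residuals, y, atol=1e-12)

    def test_rank_deficient_design_raises(self, reference):
        _, design, rdm = reference
        bad = fs.RsaDesign(
            matrix=np.column_stack([design.matrix, design.matrix[:, 0]]),
            names=design.names + ["dup"],
            condition_labels=design.condition_labels,
        )
        with pytest.raises(ValueError):
            fs.fit_rsa_regression(rdm, bad)


class TestCorrelationAndCeiling:
    def test_rdm_correlation_limits(self, reference):
        _, _, rdm = reference
        r, z = fs.rdm_correlation(rdm, rdm)
        assert r == pytest.approx(1.0)
        negated = fs.RDM(labels=rdm.labels, matrix=-rdm.matrix,
                         metric="crossvalidated")
        r2, _ = fs.rdm_correlation(rdm, negated)
        assert r2 == pytest.approx(-1.0)

    def test_fisher_z_value(self):
        assert fs.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_fisher_z_clips_and_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="facespace.rsa_inference"):
            z = fs.fisher_z(1.0)
        assert np.isfinite(z)
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_zero_variance_vector_raises(self, reference):
        _, _, rdm = reference
        flat = fs.RDM(labels=rdm.labels, matrix=np.ones((12, 12)) - np.eye(12))
        with pytest.raises(ValueError):
            fs.rdm_correlation(flat, rdm)

    def test_ceiling_near_one_for_reproducible_rdms(self, reference, rng):
        _, _, rdm = reference
        rdms = [
            fs.RDM.from_vector(rdm.vector + 0.001 * rng.standard_normal(66),
                               rdm.labels)
            for _ in range(8)
        ]
        nc = fs.noise_ceiling(rdms)
        assert nc.lower > 0.99
        assert nc.upper > 0.99
        assert nc.lower <= nc.upper

    def test_ceiling_bounds_order_and_null_behavior(self):
        lowers, uppers = [], []
        for k in range(200):
            rng = np.random.default_rng(k)
            rdms = [
                fs.RDM.from_vector(rng.standard_normal(66),
                                   [f"c{i}" for i in range(12)],
                                   metric="crossvalidated")
                for _ in range(6)
            ]
            nc = fs.noise_ceiling(rdms)
            lowers.append(nc.lower_z)
            uppers.append(nc.upper_z)
        lowers = np.asarray(lowers)
        uppers = np.asarray(uppers)
        assert np.all(lowers <= uppers)
        assert abs(np.mean(lowers)) < 0.05  # unrelated RDMs: no shared structure
        assert np.mean(uppers) > np.mean(lowers) + 0.1  # in-sample optimism

    def test_ceiling_requires_three_participants(self, reference):
        _, _, rdm = reference
        with pytest.raises(ValueError):
            fs.noise_ceiling([rdm, rdm])


class TestGridSearch:
    def test_row_major_cell_order(self):
        grid = fs.parameter_grid(a=[1, 2], b=[10, 20])
        assert grid == [
            {"a": 1, "b": 10}, {"a": 1, "b": 20},
            {"a": 2, "b": 10}, {"a": 2, "b": 20},
        ]

    def test_noise_free_parameter_recovery(self, default_grid):
        """The generating cell wins every split when data are its own RDM."""
        cells = fs.parameter_grid(o=[0.0, 1.0], s=[0.5, 4.0], p=[0.0, 0.9])
        truth = {"o": 1.0, "s": 0.5, "p": 0.9}

        def predictor(cell, seed):
            return fs.model_rdm(
                fs.RampModel(fs.RampParams(**cell), rng=seed), default_grid
            )

        seeds = [101, 102, 103, 104]
        data = [predictor(truth, seed) for seed in seeds]
        result = fs.grid_search_fit(predictor, seeds, data, cells)
        truth_index = cells.index(truth)
        assert np.all(result.winners == truth_index)
        assert result.mean_r > 0.99

    def test_empty_grid_and_misaligned_inputs(self, reference):
        _, _, rdm = reference
        with pytest.raises(ValueError):
            fs.grid_search_fit(lambda c, x: rdm, [1, 2], [rdm, rdm], [])
        with pytest.raises(ValueError):
            fs.grid_search_fit(lambda c, x: rdm, [1], [rdm, rdm], [{"a": 1}])

    def test_result_table_has_one_row_per_split(self, default_grid):
        cells = fs.parameter_grid(o=[0.0, 1.0], s=[1.0], p=[0.0])

        def predictor(cell, seed):
            return fs.model_rdm(
                fs.RampModel(fs.RampParams(**cell), rng=seed), default_grid
            )

        data = [predictor({"o": 1.0, "s": 1.0, "p": 0.0}, s) for s in (1, 2, 3)]
        result = fs.grid_search_fit(predictor, [1, 2, 3], data, cells)
        frame = result.to_frame()
        assert list(frame["left_out"]) == [0, 1, 2]
        assert {"o", "s", "p", "z", "r"} <= set(frame.columns)


class TestActivationSimilarity:
    def test_self_correlation_is_one(self, rng):
        prof = rng.uniform(size=(5, 24))
        table = fs.activation_similarity(prof, prof)
        assert np.allclose(table["r"], 1.0)

    def test_opposite_eccentricity_trends_anticorrelate(self, default_grid):
        ramp = fs.RampModel(fs.RampParams(o=1.0, s=1.0), rng=0)
        exemplar = fs.ExemplarModel(fs.ExemplarParams(w=1.0, d=1.0), rng=1)
        ramp_prof = fs.model_activation_profile(ramp, default_grid)
        ex_prof = fs.model_activation_profile(exemplar, default_grid)
        table = fs.activation_similarity(ex_prof[None], ramp_prof[None])
        assert table["r"].iloc[0] < 0

    def test_ramp_generated_profiles_yield_positive_group_effect(self, default_grid):
        rng = np.random.default_rng(2)
        model_prof = fs.model_activation_profile(
            fs.RampModel(fs.RampParams(o=1.0, s=1.0), rng=3), default_grid
        )
        data = model_prof[None] + 0.3 * model_prof.std() * rng.standard_normal((8, 24))
        table = fs.activation_similarity(np.tile(model_prof, (8, 1)), data)
        t, p = fs.one_sample_t(table["z"].to_numpy())
        assert t > 0
        assert p < 0.05

    def test_constant_profile_raises(self):
        with pytest.raises(ValueError):
            fs.activation_similarity(np.ones((1, 5)), np.random.rand(1, 5))


class TestGroupTests:
    def test_degenerate_inputs(self):
        t, p = fs.one_sample_t(np.zeros(6))
        assert (t, p) == (0.0, 1.0)
        t, p = fs.one_sample_t(np.full(6, 2.0))
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_on_regular_data(self, rng):
        x = rng.standard_normal(10) + 0.5
        t, p = fs.one_sample_t(x)
        ts, ps = stats.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ts)
        assert p == pytest.approx(ps)

    def test_statistic_monotone_in_location_shift(self, rng):
        x = rng.standard_normal(10)
        ts = [fs.one_sample_t(x + shift)[0] for shift in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(ts) > 0)

    def test_paired_t_equals_one_sample_on_differences(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(8)
        assert fs.paired_t(a, b) == fs.one_sample_t(a - b)

    def test_anova_main_effect_equals_paired_contrast(self, rng):
        frame = pd.DataFrame({
            "eccentricity_within": rng.standard_normal(10) + 1.0,
            "direction_within": rng.standard_normal(10),
            "eccentricity_across": rng.standard_normal(10) + 1.0,
            "direction_across": rng.standard_normal(10),
        })
        table = fs.anova_2x2_repeated(frame).set_index("effect")
        ecc = (frame["eccentricity_within"] + frame["eccentricity_across"]) / 2
        direc = (frame["direction_within"] + frame["direction_across"]) / 2
        t_direct, p_direct = fs.paired_t(ecc.to_numpy(), direc.to_numpy())
        assert table.loc["metric", "t"] == pytest.approx(t_direct)
        assert table.loc["metric", "p"] == pytest.approx(p_direct)


class TestFoldDependence:
    def test_reproducible_under_fixed_seed(self):
        kwargs = dict(signal_levels=[(0.0, 0.0)], n_sims=100, n_participants=6)
        a = fs.simulate_fold_dependence(rng=np.random.default_rng(1), **kwargs)
        b = fs.simulate_fold_dependence(rng=np.random.default_rng(1), **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_too_few_simulations(self):
        with pytest.raises(ValueError):
            fs.simulate_fold_dependence([(0.0, 0.0)], n_sims=10)

    def test_strong_signal_gives_full_power(self):
        table = fs.simulate_fold_dependence(
            [(2.0, 0.0)], n_sims=100, rng=np.random.default_rng(3)
        )
        assert table["model1_vs_0"].iloc[0] > 0.95
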