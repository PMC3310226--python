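import math

import numpy as np
import pytest
from scipy import stats

import exprsearch as es
from exprsearch.preprocess import bayes_t_statistics


def matrix_from(values, scale="log2"):
    values = np.asarray(values, dtype=float)
    return es.ExpressionMatrix(
        probe_ids=[f"P{i}_at" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        experiment_id="T",
        scale=scale,
    )


def groups_for(n_control, n_treated, cid="T_1"):
    return es.GroupDefinition(
        cid,
        [f"s{j}" for j in range(n_control)],
        [f"s{j}" for j in range(n_control, n_control + n_treated)],
    )


class TestFoldChange:
    def test_equal_means_give_zero(self):
        m = matrix_from([[5.0, 5.0, 5.0, 5.0]])
        assert es.compute_fold_change(m, groups_for(2, 2))["P0_at"] == 0.0

    def test_linear_quadrupling_gives_two(self):
        m = matrix_from([[100.0, 100.0, 400.0, 400.0]], scale="linear")
        assert es.compute_fold_change(m, groups_for(2, 2))["P0_at"] == pytest.approx(2.0)

    def test_linear_ratio_of_group_means(self):
        # independent arithmetic: mean(10,14)/mean(3,5) = 12/4, log2 = 1.5849625...
        m = matrix_from([[3.0, 5.0, 10.0, 14.0]], scale="linear")
        expected = math.log2((10 + 14) / 2 / ((3 + 5) / 2))
        fold = es.compute_fold_change(m, groups_for(2, 2))["P0_at"]
        assert fold == pytest.approx(expected, abs=1e-12)
        assert fold == pytest.approx(1.5849625007211562, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_antisymmetry_under_group_swap(self, seed):
        cfg = es.SimConfig(seed=seed, n_probes=50, noise_sd=0.6)
        m, (g,) = es.simulate_experiment(cfg)
        swapped = es.GroupDefinition(g.contrast_id, g.treated_samples, g.control_samples)
        fwd = es.compute_fold_change(m, g)
        rev = es.compute_fold_change(m, swapped)
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)

    def test_log2_scale_uses_mean_difference(self):
        m = matrix_from([[2.0, 4.0, 7.0, 9.0]])
        assert es.compute_fold_change(m, groups_for(2, 2))["P0_at"] == pytest.approx(5.0)


class TestBayesT:
    def test_identical_groups_give_t_zero_p_one(self):
        rng = np.random.default_rng(0)
        half = rng.normal(8, 1, size=(40, 3))
        m = matrix_from(np.hstack([half, half]))
        t, p = bayes_t_statistics(m, groups_for(3, 3))
        np.testing.assert_allclose(t.to_numpy(), 0.0, atol=1e-14)
        np.testing.assert_allclose(p.to_numpy(), 1.0, atol=1e-14)

    def test_prior_zero_reduces_to_pooled_t(self):
        """With no pseudo-observations the regularized test is the classical
        pooled two-sample t-test, probe for probe."""
        rng = np.random.default_rng(42)
        m = matrix_from(rng.normal(8, 1, size=(20, 7)))
        g = groups_for(3, 4)
        p = es.bayes_t_test(m, g, es.BayesTConfig(prior_df=0))
        ctrl = m.values[:, :3]
        trt = m.values[:, 3:]
        t_ref, p_ref = stats.ttest_ind(trt, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(p.to_numpy(), p_ref, atol=1e-10)

    def test_planted_shift_is_top_ranked_and_significant(self):
        cfg = es.SimConfig(
            seed=5, n_probes=500, noise_sd=0.1,
            planted=[es.PlantedEffect([7], 5.0, 0)],
        )
        m, (g,) = es.simulate_experiment(cfg)
        p = es.bayes_t_test(m, g)
        assert p.idxmin() == m.probe_ids[7]
        assert p.iloc[7] < 1e-4

    def test_pvalues_invariant_under_global_shift(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(30, 6))
        g = groups_for(3, 3)
        p1 = es.bayes_t_test(matrix_from(values), g)
        p2 = es.bayes_t_test(matrix_from(values + 100.0), g)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-9)

    def test_paired_mode_requires_equal_groups(self):
        m = matrix_from(np.random.default_rng(0).normal(8, 1, (5, 5)))
        with pytest.raises(es.ValidationError, match="equal group sizes"):
            es.bayes_t_test(m, groups_for(2, 3), es.BayesTConfig(paired=True))

    def test_paired_prior_zero_matches_paired_t(self):
        rng = np.random.default_rng(9)
        m = matrix_from(rng.normal(8, 1, size=(25, 6)))
        g = groups_for(3, 3)
        p = es.bayes_t_test(m, g, es.BayesTConfig(prior_df=0, paired=True))
        _, p_ref = stats.ttest_rel(m.values[:, 3:], m.values[:, :3], axis=1)
        np.testing.assert_allclose(p.to_numpy(), p_ref, atol=1e-10)

    def test_config_validation(self):
        with pytest.raises(es.ValidationError):
            es.BayesTConfig(window_size=4)
        with pytest.raises(es.ValidationError):
            es.BayesTConfig(prior_df=-1)


class TestBuildContrast:
    def test_inclusion_rule_rejects_single_arrays(self):
        m = matrix_from([[1.0, 2.0], [3.0, 4.0]])
        g = es.GroupDefinition("X_1", ["s0"], ["s1"])
        with pytest.raises(es.ValidationError, match="minimum of two control and two treated"):
            es.build_contrast(m, g)

    def test_two_by_two_experiment_builds_one_record(self):
        """The smallest admissible design: 4 arrays, 2 control + 2 treated."""
        cfg = es.SimConfig(seed=1, n_probes=100, n_control=2, n_treated=2)
        m, (g,) = es.simulate_experiment(cfg)
        rec = es.build_contrast(m, g)
        assert (rec.n_control, rec.n_treated) == (2, 2)
        assert len(rec.fold) == 100
        assert rec.pvalue.between(0, 1, inclusive="right").all()

    def test_build_is_deterministic(self):
        cfg = es.SimConfig(seed=2, n_probes=80)
        m, (g,) = es.simulate_experiment(cfg)
        r1 = es.build_contrast(m, g)
        r2 = es.build_contrast(m, g)
        assert (r1.fold == r2.fold).all()
        assert (r1.pvalue == r2.pvalue).all()
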