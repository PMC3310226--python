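import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import exprsearch as es
from conftest import make_db


class TestBhFdr:
    def test_single_pvalue_is_its_own_q(self):
        assert es.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        # each p_(j) * 4 / j equals 0.04, so every q is 0.04
        np.testing.assert_allclose(es.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_tied_pvalues_share_q(self):
        q = es.bh_fdr([0.001, 0.001, 0.5])
        assert q[0] == q[1]
        assert q[2] > q[0]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).random(37) * 0.999 + 0.001
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(es.bh_fdr(p), q_ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(es.ValidationError):
            es.bh_fdr([0.5, 0.0])
        with pytest.raises(es.ValidationError):
            es.bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=40))
    def test_invariants(self, pvals):
        p = np.array(pvals)
        q = es.bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        np.testing.assert_allclose(es.bh_fdr(p[perm]), es.bh_fdr(p)[perm], atol=1e-14)


class TestProfileSearch:
    def test_self_query_tops_ranking_at_r_one(self, demo_db, demo_signature):
        hits = es.profile_search(demo_signature, demo_db)
        assert hits[0].contrast_id == es.synthgen.EMBEDDED_CONTRAST_ID
        assert hits[0].pearson_r == pytest.approx(1.0, abs=1e-12)
        assert hits[0].rank == 1

    def test_negated_contrast_ranks_last_at_minus_one(self):
        rng = np.random.default_rng(0)
        sig_folds = rng.normal(0, 2, 10)
        folds = rng.normal(0, 1, size=(10, 5))
        folds[:, 2] = -sig_folds
        db = make_db(folds)
        sig = es.Signature(list(zip([f"P{i:04d}_at" for i in range(10)], sig_folds)))
        hits = es.profile_search(sig, db)
        assert hits[-1].contrast_id == "C0002_1"
        assert hits[-1].pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_pearson(self):
        """r agrees with an explicit covariance/variance computation."""
        rng = np.random.default_rng(7)
        x = rng.normal(0, 2, 10)
        y = rng.normal(0, 1, 10)
        db = make_db(y[:, None])
        sig = es.Signature(list(zip([f"P{i:04d}_at" for i in range(10)], x)))
        (hit,) = es.profile_search(sig, db)
        xm, ym = x - x.mean(), y - y.mean()
        r_ref = float(np.sum(xm * ym) / math.sqrt(np.sum(xm**2) * np.sum(ym**2)))
        assert hit.pearson_r == pytest.approx(r_ref, abs=1e-12)

    def test_truncates_to_top_n(self):
        folds = np.random.default_rng(1).normal(0, 1, size=(12, 50))
        db = make_db(folds)
        sig = es.Signature([(f"P{i:04d}_at", float(i - 6)) for i in range(12)])
        assert len(es.profile_search(sig, db)) == 30
        assert len(es.profile_search(sig, db, es.SearchConfig(top_n=7))) == 7
        # fewer valid contrasts than top_n: all of them, no padding
        small = make_db(folds[:, :4])
        assert len(es.profile_search(sig, small)) == 4

    def test_missing_values_skipped_not_zero_filled(self):
        folds = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, np.nan]])
        db = make_db(folds)
        sig = es.Signature([("P0000_at", 1.0), ("P0001_at", 2.0), ("P0002_at", 3.0), ("P0003_at", -9.0)])
        hits = {h.contrast_id: h for h in es.profile_search(sig, db)}
        # contrast 1 only overlaps on the 3 perfectly collinear probes
        assert hits["C0001_1"].n_overlap == 3
        assert hits["C0001_1"].pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_no_overlap_raises_listing_unmatched(self, demo_db):
        sig = es.Signature([("nope1", 1.0), ("nope2", 2.0), ("nope3", -1.0)])
        with pytest.raises(es.EmptyResultError) as err:
            es.profile_search(sig, demo_db)
        assert set(err.value.unmatched) == {"nope1", "nope2", "nope3"}

    def test_zero_variance_contrast_excluded(self):
        folds = np.column_stack([np.zeros(5), np.arange(5.0)])
        db = make_db(folds)
        sig = es.Signature([(f"P{i:04d}_at", float(i)) for i in range(5)])
        hits = es.profile_search(sig, db)
        assert [h.contrast_id for h in hits] == ["C0001_1"]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 8)
        db1 = make_db(y[:, None])
        db2 = make_db((3.5 * y + 2.0)[:, None])
        sig = es.Signature(list(zip([f"P{i:04d}_at" for i in range(8)], rng.normal(0, 1, 8))))
        r1 = es.profile_search(sig, db1)[0].pearson_r
        r2 = es.profile_search(sig, db2)[0].pearson_r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestProbeListSearch:
    probes4 = [f"P{i:04d}_at" for i in range(4)]

    def test_one_sample_formula_oracle(self):
        """t = mean / (sd / sqrt(k)), p two-tailed on k-1 df, recomputed directly."""
        from scipy import stats

        folds = np.zeros((4, 2))
        folds[:, 0] = [2.0, 2.2, 1.8, 2.0]
        folds[:, 1] = [0.1, -0.1, 0.05, -0.05]
        db = make_db(folds)
        hits = es.probe_list_search(self.probes4, db)
        x = np.array([2.0, 2.2, 1.8, 2.0])
        t_ref = x.mean() / (x.std(ddof=1) / 2.0)
        p_ref = 2 * stats.t.sf(abs(t_ref), 3)
        hit = next(h for h in hits if h.contrast_id == "C0000_1")
        assert hit.t_statistic == pytest.approx(t_ref, abs=1e-10)
        assert hit.p_value == pytest.approx(p_ref, abs=1e-10)
        assert hit.q_value >= hit.p_value

    def test_zero_folds_are_not_hits(self):
        folds = np.zeros((5, 1))
        folds[4, 0] = 3.0  # a non-listed probe moves; the listed four do not
        db = make_db(folds)
        hits = es.probe_list_search(self.probes4, db)
        assert hits == []

    def test_alpha_filter_and_sorting(self):
        rng = np.random.default_rng(2)
        folds = rng.normal(0, 0.5, size=(12, 100))
        folds[:, 10] += 4.0
        db = make_db(folds)
        hits = es.probe_list_search([f"P{i:04d}_at" for i in range(12)], db)
        assert all(h.p_value < 0.05 for h in hits)
        assert hits[0].contrast_id == "C0010_1"
        assert hits[0].t_statistic > 0
        ps = [h.p_value for h in hits]
        assert ps == sorted(ps)

    def test_negating_database_negates_t_preserves_p_and_q(self):
        rng = np.random.default_rng(4)
        folds = rng.normal(0.4, 0.8, size=(10, 30))
        probes = [f"P{i:04d}_at" for i in range(10)]
        cfg = es.SearchConfig(alpha=0.9999)
        up = {h.contrast_id: h for h in es.probe_list_search(probes, make_db(folds), cfg)}
        down = {h.contrast_id: h for h in es.probe_list_search(probes, make_db(-folds), cfg)}
        assert set(up) == set(down)
        for cid in up:
            assert up[cid].t_statistic == pytest.approx(-down[cid].t_statistic, abs=1e-12)
            assert up[cid].p_value == pytest.approx(down[cid].p_value, abs=1e-12)
            assert up[cid].q_value == pytest.approx(down[cid].q_value, abs=1e-12)

    def test_background_mode_flags_shifted_contrast(self):
        rng = np.random.default_rng(6)
        folds = rng.normal(0, 0.5, size=(8, 50))
        folds[:, 3] += 3.0
        db = make_db(folds)
        cfg = es.SearchConfig(gene_list_mode="background")
        hits = es.probe_list_search([f"P{i:04d}_at" for i in range(8)], db, cfg)
        assert hits[0].contrast_id == "C0003_1"
        assert hits[0].t_statistic > 0

    def test_type_one_error_near_nominal_on_null(self):
        """On null databases the share of contrasts with p < alpha is ~alpha."""
        tested = rejected = 0
        for seed in range(5):
            db = es.simulate_fold_database(seed=900 + seed, n_probes=12, n_contrasts=400)
            hits = es.probe_list_search([f"{200000+i}_at" for i in range(12)], db)
            tested += 400
            rejected += len(hits)
        frac = rejected / tested
        sd = math.sqrt(0.05 * 0.95 / tested)
        assert abs(frac - 0.05) < 4 * sd

    def test_too_few_matched_probes_raises(self, demo_db):
        with pytest.raises(es.EmptyResultError):
            es.probe_list_search(["absent_at", "also_absent_at"], demo_db)


class TestConfigValidation:
    def test_rejects_bad_settings(self):
        for kwargs in ({"top_n": 0}, {"alpha": 0.0}, {"alpha": 1.0},
                       {"min_overlap": 2}, {"gene_list_mode": "median"}):
            with pytest.raises(es.ValidationError):
                es.SearchConfig(**kwargs)
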