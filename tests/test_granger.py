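"""VAR fitting, Geweke decomposition, maps, thresholds, group stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from closurenet.granger import (
    compute_dgcm,
    condition_segments,
    fit_var,
    geweke_measures,
    group_gci_stats,
    select_var_order,
    signed_rank_test,
    threshold_map,
)
from closurenet.design import SessionDesign, build_fmri_session


def _var1_series(A, n, rng, burn=100):
    k = A.shape[0]
    x = np.zeros((n + burn, k))
    u = rng.standard_normal((n + burn, k))
    for t in range(1, n + burn):
        x[t] = A @ x[t - 1] + u[t]
    return x[burn:]


def _lagged_pair(n, rng, a=1.0):
    """y[t] = a*x[t-1] + e[t]; population F_x->y = ln(1 + a^2)."""
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = np.empty(n)
    y[0] = e[0]
    y[1:] = a * x[:-1] + e[1:]
    return x, y


class TestFitVar:
    def test_recovery_from_known_var1(self, rng):
        A = np.array([[0.5, 0.2, 0.0], [0.0, 0.4, -0.3], [0.1, 0.0, 0.3]])
        X = _var1_series(A, 5000, rng)
        model = fit_var(X, 1)
        assert np.abs(model.a_effective[0] - A).max() < 0.05
        # stored minus-convention: a_minus = -a_effective
        np.testing.assert_allclose(model.a_minus[0], -model.a_effective[0])

    def test_white_noise_coefficients_within_3_se(self, rng):
        X = rng.standard_normal((2000, 3))
        model = fit_var(X, 2)
        for a, se in zip(model.a_effective, model.coef_se()):
            assert np.all(np.abs(a) < 3.5 * se)

    def test_refit_on_own_reconstruction_is_self_consistent(self, rng):
        A = np.array([[0.6, 0.2], [-0.1, 0.5]])
        X = _var1_series(A, 800, rng)
        model = fit_var(X, 1)
        # rebuild the series from the fitted coefficients + residuals
        Xd = X - model.mean
        rec = np.zeros_like(Xd)
        rec[0] = Xd[0]
        for t in range(1, len(Xd)):
            rec[t] = model.a_effective[0] @ rec[t - 1] + model.residuals[t - 1]
        refit = fit_var(rec + model.mean, 1)
        np.testing.assert_allclose(refit.a_effective[0], model.a_effective[0], atol=1e-8)

    def test_matches_statsmodels_var(self, rng):
        from statsmodels.tsa.api import VAR

        X = _var1_series(np.array([[0.5, 0.1], [0.2, 0.3]]), 600, rng)
        mine = fit_var(X, 1)
        ref = VAR(X - X.mean(axis=0)).fit(1, trend="n")
        np.testing.assert_allclose(mine.a_effective[0], ref.coefs[0], atol=1e-8)

    def test_too_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            fit_var(np.zeros((5, 3)), 2)

    def test_order_selection_recovers_var1(self, rng):
        X = _var1_series(np.array([[0.7, 0.0], [0.3, 0.5]]), 2000, rng)
        assert select_var_order(X, max_p=4) == 1


class TestGewekeMeasures:
    def test_independent_white_noise_near_zero(self, rng):
        x = rng.standard_normal(10000)
        y = rng.standard_normal(10000)
        res = geweke_measures(x, y, p=1)
        assert res.f_x_to_y < 0.01
        assert res.f_y_to_x < 0.01
        assert res.f_instantaneous < 0.01

    def test_lagged_copy_converges_to_ln2(self, rng):
        x, y = _lagged_pair(50000, rng)
        res = geweke_measures(x, y, p=1)
        assert res.f_x_to_y == pytest.approx(np.log(2), abs=0.02)
        assert res.f_y_to_x == pytest.approx(0.0, abs=0.01)

    def test_additivity_identity(self, rng):
        x, y = _lagged_pair(3000, rng, a=0.7)
        res = geweke_measures(x, y, p=2)
        assert res.f_total == pytest.approx(
            res.f_x_to_y + res.f_y_to_x + res.f_instantaneous, abs=1e-6)

    def test_swap_exchanges_directed_terms_exactly(self, rng):
        x, y = _lagged_pair(1500, rng, a=0.5)
        fwd = geweke_measures(x, y, p=1)
        rev = geweke_measures(y, x, p=1)
        assert rev.f_x_to_y == fwd.f_y_to_x
        assert rev.f_y_to_x == fwd.f_x_to_y
        assert rev.f_instantaneous == fwd.f_instantaneous
        assert rev.dgci == -fwd.dgci

    @given(seed=st.integers(0, 10_000), a=st.floats(0.0, 1.5),
           scale=st.floats(0.1, 10.0))
    def test_nonnegativity_and_scale_invariance(self, seed, a, scale):
        rng = np.random.default_rng(seed)
        x, y = _lagged_pair(400, rng, a=a)
        res = geweke_measures(x, y, p=1)
        for val in (res.f_x_to_y, res.f_y_to_x, res.f_instantaneous):
            assert val >= -1e-10
        scaled = geweke_measures(scale * x, y, p=1)
        assert scaled.f_x_to_y == pytest.approx(res.f_x_to_y, abs=1e-9)
        assert scaled.f_y_to_x == pytest.approx(res.f_y_to_x, abs=1e-9)

    def test_instantaneous_dependence_detected(self, rng):
        z = rng.standard_normal(5000)
        x = z + 0.3 * rng.standard_normal(5000)
        y = z + 0.3 * rng.standard_normal(5000)
        res = geweke_measures(x, y, p=1)
        assert res.f_instantaneous > 0.5
        assert res.f_x_to_y < 0.05

    def test_length_mismatch_and_short_series_errors(self):
        with pytest.raises(ValueError):
            geweke_measures(np.zeros(10), np.zeros(11), p=1)
        with pytest.raises(ValueError):
            geweke_measures(np.zeros(6), np.zeros(6), p=1)


class TestComputeDgcm:
    def test_driven_voxel_positive_reference_negative_reverse(self, rng):
        T, V = 1000, 30
        x = rng.standard_normal(T)
        vol = np.column_stack([x, rng.standard_normal((T, V - 1))])
        vol[1:, 5] = x[:-1] + rng.standard_normal(T - 1)   # ROI drives voxel 5
        vol[:-1, 7] += 0.0                                  # placeholder
        dmap = compute_dgcm(np.array([0]), vol, p=1)
        assert dmap.dgci[5] > 0.3
        # voxel that drives the reference: x depends on voxel 9's past
        vol2 = vol.copy()
        drv = rng.standard_normal(T)
        vol2[:, 9] = drv
        vol2[1:, 0] = drv[:-1] + rng.standard_normal(T - 1)
        dmap2 = compute_dgcm(np.array([0]), vol2, p=1)
        assert dmap2.dgci[9] < -0.3

    def test_null_volume_small_mean_dgci(self, rng):
        vol = rng.standard_normal((1000, 50))
        dmap = compute_dgcm(np.array([0, 1]), vol, p=1)
        vals = dmap.dgci[~dmap.ref_flag]
        assert np.abs(vals).mean() < 0.02

    def test_reference_voxels_flagged_not_computed(self, rng):
        vol = rng.standard_normal((300, 20))
        dmap = compute_dgcm(np.array([2, 3]), vol, p=1)
        assert dmap.ref_flag[[2, 3]].all()
        assert np.isnan(dmap.dgci[[2, 3]]).all()
        assert np.isfinite(dmap.dgci[~dmap.ref_flag]).all()

    def test_segments_exclude_cross_boundary_pairs(self, rng):
        # dependence exists only across the segment boundary: restricting
        # to segments must remove it
        T = 400
        x = rng.standard_normal(T)
        y = rng.standard_normal(T)
        y[200] = 5 * x[199]  # single cross-boundary dependence
        vol = np.column_stack([x, y])
        whole = compute_dgcm(np.array([0]), vol, p=1)
        split = compute_dgcm(np.array([0]), vol, p=1,
                             segments=[(0, 200), (200, 400)])
        assert split.n_used == whole.n_used - 1

    def test_short_segment_skipped_with_warning(self, rng):
        vol = rng.standard_normal((100, 5))
        with pytest.warns(UserWarning):
            dmap = compute_dgcm(np.array([0]), vol, p=2,
                                segments=[(0, 3), (10, 100)])
        assert dmap.n_used == 88

    def test_condition_segments_from_design(self):
        ses = build_fmri_session(2, 3, 0)
        segs = condition_segments(ses, "primed", p=1)
        assert len(segs) == 2
        for start, stop in segs:
            assert stop - start == 10  # 9 TRs + 1 lead-in
        with pytest.raises(ValueError):
            condition_segments(SessionDesign(schedule=("rest",) * 20), "primed", 1)


class TestThresholdMap:
    def test_same_seed_identical_mask(self, rng):
        vol = rng.standard_normal((400, 40))
        a = threshold_map(compute_dgcm(np.array([0]), vol, p=1), B=100, q=0.05, seed=9)
        b = threshold_map(compute_dgcm(np.array([0]), vol, p=1), B=100, q=0.05, seed=9)
        np.testing.assert_array_equal(a.sig_mask, b.sig_mask)
        np.testing.assert_array_equal(a.pvals, b.pvals)

    def test_planted_voxel_detected_nulls_not(self, rng):
        T = 600
        x = rng.standard_normal(T)
        vol = np.column_stack([x, rng.standard_normal((T, 99))])
        vol[1:, 1] = x[:-1] + rng.standard_normal(T - 1)
        dmap = threshold_map(compute_dgcm(np.array([0]), vol, p=1),
                             B=200, q=0.05, seed=3)
        assert dmap.sig_mask[1]
        assert dmap.sig_mask.sum() <= 3

    def test_b_constraints(self, rng):
        vol = rng.standard_normal((200, 10))
        dmap = compute_dgcm(np.array([0]), vol, p=1)
        with pytest.raises(ValueError):
            threshold_map(dmap, B=50, q=0.05, seed=0)
        with pytest.raises(ValueError):
            threshold_map(dmap, B=100, q=0.005, seed=0)


def _exact_signed_rank_p(values):
    """Exhaustive two-sided signed-rank p over all 2^n sign assignments."""
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    n = len(v)
    mu = ranks.sum() / 2
    stat_obs = abs(w_obs - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += abs(w - mu) >= stat_obs - 1e-12
    return count / 2 ** n


class TestGroupStats:
    def test_median_and_iqr_definition(self):
        df = pd.DataFrame({"subject": list("abcde"), "group": "g1",
                           "connection": "DS->PFC", "value": [1.0, 2, 3, 4, 5]})
        res = group_gci_stats(df, min_per_group=5).iloc[0]
        assert res["median"] == 3.0
        assert res["iqr"] == 2.0

    def test_all_positive_n6_exact_p(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert signed_rank_test(vals) == pytest.approx(2 / 64)
        assert _exact_signed_rank_p(vals) == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle_on_mixed_sample(self, rng):
        vals = rng.normal(0.3, 1.0, size=9)
        while len(np.unique(np.abs(vals))) < len(vals) or np.any(vals == 0):
            vals = rng.normal(0.3, 1.0, size=9)
        assert signed_rank_test(vals) == pytest.approx(_exact_signed_rank_p(vals), abs=1e-12)

    def test_all_zero_undefined(self):
        assert np.isnan(signed_rank_test(np.zeros(8)))

    def test_rank_sum_type_i_error_calibrated(self):
        rng = np.random.default_rng(77)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            rej += stats.ranksums(a, b).pvalue < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_group_table_shapes_and_small_group_error(self, rng):
        rows = []
        for g in ("control", "patient"):
            for s in range(6):
                rows.append({"subject": f"{g}{s}", "group": g,
                             "connection": "DS->PFC",
                             "value": rng.normal(0.2 if g == "control" else 0.0, 0.1)})
        res = group_gci_stats(pd.DataFrame(rows))
        assert len(res) == 2
        assert res["p_rank_sum"].nunique() == 1
        with pytest.raises(ValueError):
            group_gci_stats(pd.DataFrame(rows).iloc[:8], min_per_group=5)
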