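"""Unit and property tests for the two-way FE weighted estimator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import heatfe
from heatfe.panel_core import (
    CollinearityError,
    _group_codes,
    absorbed_dof,
    cluster_vcov,
    gaussian_aic,
    within_demean,
)

from conftest import brute_force_cluster_vcov, dummy_wls_slopes, random_small_panel


# ---------------------------------------------------------------------------
# within_demean


def test_single_dimension_demean_equals_direct_group_mean_subtraction():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    codes = rng.integers(0, 5, size=40)
    w = rng.uniform(0.5, 2.0, size=40)
    out, iters = within_demean(x, [codes], weights=w)
    direct = x - np.array(
        [np.average(x[codes == g], weights=w[codes == g]) for g in codes]
    )
    np.testing.assert_allclose(out, direct, atol=1e-12)
    assert iters == 1


def test_values_constant_within_groups_demean_to_zero():
    codes = np.repeat(np.arange(4), 5)
    x = codes.astype(float) * 3.7 + 1.0
    out, _ = within_demean(x, [codes, np.tile(np.arange(5), 4)])
    np.testing.assert_allclose(out, 0.0, atol=1e-9)


def test_crossed_demeaning_matches_dummy_regression_residual_on_toy_panel():
    # 6-row panel, two crossed FE dims, unit weights
    f1 = np.array([0, 0, 1, 1, 2, 2])
    f2 = np.array([0, 1, 0, 1, 0, 1])
    x = np.array([3.0, -1.0, 4.0, 1.5, -2.0, 0.5])
    out, _ = within_demean(x, [f1, f2], tol=1e-13)
    D = np.column_stack(
        [(f1 == g).astype(float) for g in range(3)]
        + [(f2 == g).astype(float) for g in range(2)]
    )
    coef, *_ = np.linalg.lstsq(D, x, rcond=None)
    np.testing.assert_allclose(out, x - D @ coef, atol=1e-10)


def test_demeaned_columns_orthogonal_to_group_indicators():
    rng = np.random.default_rng(3)
    n = 200
    codes = [rng.integers(0, 12, n), rng.integers(0, 7, n)]
    w = rng.uniform(1, 100, n)
    X = rng.normal(size=(n, 3))
    out, _ = within_demean(X, codes, weights=w, tol=1e-12)
    for c in codes:
        sums = np.zeros((c.max() + 1, 3))
        np.add.at(sums, c, out * w[:, None])
        assert np.abs(sums).max() < 1e-7 * w.max()


def test_nonconvergence_raises_with_last_delta():
    rng = np.random.default_rng(1)
    n = 50
    codes = [rng.integers(0, 20, n), rng.integers(0, 20, n)]
    with pytest.raises(heatfe.ConvergenceError, match="adjustment"):
        within_demean(rng.normal(size=n), codes, tol=1e-14, max_iter=1)


# ---------------------------------------------------------------------------
# fit


def test_no_fe_unit_weights_equals_textbook_ols_line():
    panel = pd.DataFrame(
        {"y": [2.0, 4.0, 6.0, 8.0, 10.0], "x": [1.0, 2.0, 3.0, 4.0, 5.0]}
    )
    spec = heatfe.FESpec(response="y", regressors=["x"], fe_groups=[],
                         cluster=None)
    res = heatfe.fit(panel, spec)
    assert res.coef[0] == pytest.approx(2.0, abs=1e-12)


def test_fe_estimator_recovers_truth_where_pooled_ols_is_biased(fe_spec):
    cfg = heatfe.PanelDGPConfig(
        n_counties=100, n_states=10, years=(2013, 2022), beta_temp=1.5,
        confounded=True, seed=42,
    )
    panel, truth = heatfe.generate_panel(cfg)
    res = heatfe.fit(panel, fe_spec)
    b, se = res.coef[0], res.se[0]
    assert b - 1.96 * se <= truth["beta_temp"] <= b + 1.96 * se
    pooled = heatfe.fit(panel, replace(fe_spec, fe_groups=[]))
    # pooled OLS inherits the FE-temperature confounding: its own CI
    # excludes the truth
    assert abs(pooled.coef[0] - truth["beta_temp"]) > 1.96 * pooled.se[0]


def test_crossed_fe_population_weights_match_dense_dummy_wls():
    cfg = heatfe.PanelDGPConfig(n_counties=3, n_states=2, years=(2013, 2014),
                                seed=9)
    panel, _ = heatfe.generate_panel(cfg)
    res = heatfe.fit(panel, heatfe.default_fe_spec())
    oracle = dummy_wls_slopes(
        panel, "death_rate", ["temp", "precip"],
        [("county_id", "month"), ("state_id", "year")], weights="population",
    )
    np.testing.assert_allclose(res.coef, oracle, atol=1e-8)


@given(st.integers(0, 10_000))
def test_fe_estimator_equals_dummy_wls_on_random_panels(seed):
    """Property: alternating projections == dense dummy WLS (rel tol 1e-8)."""
    rng = np.random.default_rng(seed)
    panel = random_small_panel(rng)
    res = heatfe.fit(panel, heatfe.default_fe_spec())
    oracle = dummy_wls_slopes(
        panel, "death_rate", ["temp", "precip"],
        [("county_id", "month"), ("state_id", "year")], weights="population",
    )
    np.testing.assert_allclose(res.coef, oracle, rtol=1e-8, atol=1e-10)


def test_coefficients_invariant_to_constant_shift_within_fe_span(
    small_confounded_panel, fe_spec
):
    panel, _ = small_confounded_panel
    res0 = heatfe.fit(panel, fe_spec)
    shifted = panel.copy()
    # add a county-month-cell specific constant: lies in the absorbed span
    key = shifted["county_id"].astype(str) + "_" + shifted["month"].astype(str)
    offsets = {k: v for v, k in enumerate(sorted(key.unique()))}
    shifted["death_rate"] = shifted["death_rate"] + key.map(offsets) * 7.3
    res1 = heatfe.fit(shifted, fe_spec)
    np.testing.assert_allclose(res0.coef, res1.coef, rtol=1e-7, atol=1e-8)


def test_doubling_weights_leaves_coefficients_and_vcov_unchanged(
    small_confounded_panel, fe_spec
):
    panel, _ = small_confounded_panel
    res0 = heatfe.fit(panel, fe_spec)
    doubled = panel.assign(population=panel["population"] * 2)
    res1 = heatfe.fit(doubled, fe_spec)
    np.testing.assert_allclose(res0.coef, res1.coef, rtol=1e-9)
    np.testing.assert_allclose(res0.vcov, res1.vcov, rtol=1e-8)


def test_collinear_regressor_is_named_in_error(small_confounded_panel, fe_spec):
    panel, _ = small_confounded_panel
    bad = panel.copy()
    # constant within county-month cells -> absorbed by the FE
    bad["cell_const"] = (
        bad["county_id"].astype("category").cat.codes * 10 + bad["month"]
    ).astype(float)
    spec = replace(fe_spec, regressors=["temp", "precip", "cell_const"])
    with pytest.raises(CollinearityError, match="cell_const"):
        heatfe.fit(bad, spec)


def test_absorbed_dof_equals_dummy_design_rank():
    rng = np.random.default_rng(7)
    panel = random_small_panel(rng)
    codes = [
        _group_codes(panel, ("county_id", "month")),
        _group_codes(panel, ("state_id", "year")),
    ]
    d1 = pd.get_dummies(codes[0]).to_numpy(dtype=float)
    d2 = pd.get_dummies(codes[1]).to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([d1, d2]))
    assert absorbed_dof(codes) == rank


# ---------------------------------------------------------------------------
# cluster_vcov


def test_cluster_vcov_matches_brute_force_sum_over_clusters():
    rng = np.random.default_rng(11)
    for _ in range(5):
        n, k = 60, 3
        X = rng.normal(size=(n, k))
        e = rng.normal(size=n)
        w = rng.uniform(0.5, 3.0, size=n)
        cl = rng.integers(0, 8, size=n)
        got = cluster_vcov(X, e, w, cl, dof_fe=4)
        want = brute_force_cluster_vcov(X, e, w, cl, dof_fe=4)
        np.testing.assert_allclose(got, want, atol=1e-10)


def test_singleton_clusters_reduce_to_hc1():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    n = 50
    X = rng.normal(size=(n, 2))
    y = X @ [1.0, -0.5] + rng.normal(size=n)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    V = cluster_vcov(X, e, np.ones(n), np.arange(n), dof_fe=0)
    hc1 = sm.OLS(y, X).fit(cov_type="HC1").cov_params()
    np.testing.assert_allclose(V, hc1, rtol=1e-8)


def test_point_estimates_invariant_to_row_duplication(fe_spec):
    cfg = heatfe.PanelDGPConfig(n_counties=6, n_states=3, years=(2013, 2014),
                                seed=21)
    panel, _ = heatfe.generate_panel(cfg)
    res0 = heatfe.fit(panel, fe_spec)
    dup = panel.copy()
    dup["county_id"] = dup["county_id"] + "_dup"
    doubled = pd.concat([panel, dup], ignore_index=True)
    res1 = heatfe.fit(doubled, fe_spec)
    np.testing.assert_allclose(res0.coef, res1.coef, rtol=1e-8)


def test_single_cluster_errors():
    with pytest.raises(ValueError, match="2 clusters"):
        cluster_vcov(np.ones((5, 1)), np.zeros(5), np.ones(5), np.zeros(5, int))


def test_vcov_is_symmetric_positive_semidefinite(small_confounded_panel, fe_spec):
    panel, _ = small_confounded_panel
    res = heatfe.fit(panel, fe_spec)
    np.testing.assert_allclose(res.vcov, res.vcov.T)
    assert np.all(np.linalg.eigvalsh(res.vcov) >= -1e-12)


# ---------------------------------------------------------------------------
# AIC


def test_aic_penalty_arithmetic_for_zero_added_explanatory_power():
    # same SSR, one extra parameter -> AIC larger by exactly 2
    assert gaussian_aic(10.0, 100, 3) - gaussian_aic(10.0, 100, 2) == pytest.approx(2.0)


def test_identical_refit_gives_identical_aic(small_confounded_panel, fe_spec):
    panel, _ = small_confounded_panel
    a = heatfe.fit(panel, fe_spec)
    b = heatfe.fit(panel, fe_spec)
    assert a.aic == b.aic
    assert heatfe.aic(a) == a.aic


def test_zero_ssr_rejected():
    with pytest.raises(ValueError, match="SSR"):
        gaussian_aic(0.0, 10, 1)
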