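"""Shared fixtures and independent oracles for the heatfe test suite.

The oracles here deliberately avoid the code paths they check: the FE
estimator is validated against a dense dummy-variable WLS solved by
``numpy.linalg.lstsq``, and the cluster sandwich against a literal
sum-over-clusters implementation with explicit per-cluster matrix products.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import heatfe

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def dummy_wls_slopes(panel, response, regressors, fe_groups, weights=None):
    """Brute-force oracle: WLS on the full dummy-variable design, slopes only."""
    dummies = []
    for g in fe_groups:
        cols = [g] if isinstance(g, str) else list(g)
        key = panel[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + "_" + panel[c].astype(str)
        dummies.append(pd.get_dummies(key, dtype=float).to_numpy())
    X = np.column_stack([panel[list(regressors)].to_numpy(dtype=float)] + dummies) \
        if dummies else np.column_stack(
            [panel[list(regressors)].to_numpy(dtype=float), np.ones(len(panel))]
        )
    y = panel[response].to_numpy(dtype=float)
    w = (panel[weights].to_numpy(dtype=float) if weights else np.ones(len(panel)))
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta[: len(regressors)]


def brute_force_cluster_vcov(X, resid, weights, clusters, dof_fe=0):
    """Independent CR1 sandwich: explicit loop over clusters."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    w = np.asarray(weights, dtype=float)
    e = np.asarray(resid, dtype=float)
    bread = np.linalg.inv(X.T @ np.diag(w) @ X)
    meat = np.zeros((k, k))
    for g in np.unique(clusters):
        idx = np.flatnonzero(clusters == g)
        s = np.zeros(k)
        for i in idx:
            s = s + w[i] * e[i] * X[i]
        meat += np.outer(s, s)
    G = len(np.unique(clusters))
    K = k + dof_fe
    c = (G / (G - 1)) * ((n - 1) / (n - K))
    return c * bread @ meat @ bread


def random_small_panel(rng, max_counties=8, max_years=4):
    """A small random county-month panel for oracle-equivalence checks."""
    nc = int(rng.integers(3, max_counties + 1))
    ns = int(rng.integers(2, nc + 1))
    y1 = 2013 + int(rng.integers(1, max_years))
    cfg = heatfe.PanelDGPConfig(
        n_counties=nc,
        n_states=ns,
        years=(2013, y1),
        beta_temp=float(rng.normal(1.0, 0.5)),
        confounded=bool(rng.integers(2)),
        seed=int(rng.integers(2**31 - 1)),
    )
    panel, _ = heatfe.generate_panel(cfg)
    return panel


@pytest.fixture(scope="session")
def small_confounded_panel():
    cfg = heatfe.PanelDGPConfig(
        n_counties=30, n_states=5, years=(2013, 2018), beta_temp=1.5,
        confounded=True, seed=42,
    )
    panel, truth = heatfe.generate_panel(cfg)
    return panel, truth


@pytest.fixture()
def fe_spec():
    return heatfe.default_fe_spec()
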