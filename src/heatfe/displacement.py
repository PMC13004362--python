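"""Displacement (lag/lead) effects of temperature on the death rate.

The displacement model augments the linear fixed-effects model with the
previous and following months' exposures,

    y = sum_L ( g_L temp_{m-L} + b_L precip_{m-L} ) + d_im + a_st + e ,

where L = 1 is the previous month and L = -1 the next month (a lead).  The
net (overall) effect is the sum of the current and previous month's
temperature coefficients, g_0 + g_1, with its standard error taken from the
cluster-robust covariance of the joint fit.  A +/-2-month window supports
checking that the one-month window captures the full displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panel_core import FEFitResult, FESpec, Z95, fit

logger = logging.getLogger("heatfe.displacement")


@dataclass(frozen=True)
class LagSpec:
    """Ordered set of lags applied to temperature and precipitation.

    Positive lags look back (previous months), negative lags forward
    (leads).  Lag 0 (the current month) must be included.
    """

    lags: tuple = (-1, 0, 1)

    def __post_init__(self):
        lags = tuple(sorted(int(x) for x in self.lags))
        if 0 not in lags:
            raise ValueError("lag 0 (current month) must be included")
        if len(set(lags)) != len(lags):
            raise ValueError("duplicate lags")
        object.__setattr__(self, "lags", lags)

    def column(self, base: str, lag: int) -> str:
        if lag == 0:
            return base
        return f"{base}_lag{lag}" if lag > 0 else f"{base}_lead{-lag}"

    def columns(self, bases=("temp", "precip")) -> list:
        return [self.column(b, L) for b in bases for L in self.lags]


def _month_index(panel: pd.DataFrame) -> np.ndarray:
    return panel["year"].to_numpy() * 12 + (panel["month"].to_numpy() - 1)


def add_lags(
    panel: pd.DataFrame,
    lag_spec: LagSpec,
    variables=("temp", "precip"),
) -> pd.DataFrame:
    """Attach shifted exposure columns and drop rows whose required
    lags/leads fall outside the panel.

    Lag L of a variable for row (county, m) is that county's value at
    calendar month m - L.  Shifts never cross county boundaries; a gap in a
    county's month sequence is an error (silent shifting across gaps would
    mislabel exposures).
    """
    panel = panel.sort_values(["county_id", "year", "month"]).reset_index(drop=True)
    midx = _month_index(panel)
    gaps = []
    for county, grp in panel.groupby("county_id", sort=False):
        mi = midx[grp.index]
        d = np.diff(mi)
        if np.any(d != 1):
            where = np.flatnonzero(d != 1)
            gaps.append((county, [int(mi[j]) for j in where]))
    if gaps:
        raise ValueError(f"gaps in county month sequences: {gaps}")

    out = panel.copy()
    grouped = out.groupby("county_id", sort=False)
    for var in variables:
        for L in lag_spec.lags:
            if L == 0:
                continue
            out[lag_spec.column(var, L)] = grouped[var].shift(L)

    needed = [c for c in lag_spec.columns(variables) if c in out.columns]
    complete = out[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d rows lacking a requested lag/lead", n_dropped)
    return out[complete].reset_index(drop=True)


def fit_displacement(
    panel: pd.DataFrame,
    lag_spec: LagSpec,
    fe_spec: FESpec,
) -> FEFitResult:
    """Fit the displacement model: lagged temperature and precipitation
    terms under the standard FE / weights / clustering.

    ``fe_spec.regressors`` is ignored; the regressor set is derived from
    ``lag_spec`` (temperature and precipitation at every requested lag).
    """
    work = add_lags(panel, lag_spec)
    spec = replace(fe_spec, regressors=lag_spec.columns())
    return fit(work, spec)


@dataclass
class NetEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    components: dict


def net_effect(result: FEFitResult, lag_spec: LagSpec | None = None) -> NetEffect:
    """Overall temperature effect: current plus previous month.

    estimate = g0_hat + g1_hat; SE = sqrt(V00 + V11 + 2 V01) from the
    cluster-robust covariance; 95% CI at +/- 1.96 SE.
    """
    spec = lag_spec or LagSpec((-1, 0, 1))
    names = [spec.column("temp", 0), spec.column("temp", 1)]
    missing = [n for n in names if n not in result.names]
    if missing:
        raise ValueError(f"fit lacks lag coefficients: {missing}")
    idx = [result.names.index(n) for n in names]
    g = result.coef[idx]
    V = result.vcov[np.ix_(idx, idx)]
    est = float(g.sum())
    se = float(np.sqrt(V[0, 0] + V[1, 1] + 2 * V[0, 1]))
    return NetEffect(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        components={names[0]: float(g[0]), names[1]: float(g[1])},
    )
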