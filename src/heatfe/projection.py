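"""Projection of cumulative excess police-violence deaths under future
warming, with bootstrap x climate-model Monte Carlo uncertainty.

Given a per-county, per-climate-model warming amount (the difference between
a future-period and a baseline-period mean temperature), a per-county annual
population path, and the fitted net temperature effect beta (current plus
previous month, in death-rate units per 1C), the cumulative excess deaths
attributable to warming through year T are

    E = sum_{t=base..T} sum_c pop_ct * dT_ct * beta * months_per_year ,

where beta is a monthly rate coefficient, so the per-year excess multiplies
by 12 by default (configurable).  Within the horizon the warming path
defaults to a linear ramp from 0 at the base year to the model's end-of-
horizon value; a step path is available as an alternative.

Uncertainty combines (a) a county-level cluster bootstrap of the historical
panel — counties resampled with replacement, the displacement model refit,
and the net beta recorded per draw — and (b) the spread across climate
models: B bootstrap draws crossed with M models give B*M trajectories, from
which the median, interquartile range and 95% band are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .displacement import LagSpec, fit_displacement, net_effect
from .panel_core import FESpec
from .synthetic_data import RATE_SCALE

logger = logging.getLogger("heatfe.projection")


def grid_to_county(grid_deltas: pd.DataFrame, overlaps: pd.DataFrame) -> pd.DataFrame:
    """Aggregate grid-cell warming to counties by overlap-weighted means.

    ``grid_deltas``: columns model, cell, delta_t.  ``overlaps``: columns
    county_id, cell, weight (each cell's contribution to the county;
    renormalized per county).  Counties with zero total overlap raise.
    """
    w = overlaps.copy()
    totals = w.groupby("county_id")["weight"].sum()
    bad = totals[totals <= 0].index.tolist()
    if bad:
        raise ValueError(f"counties with no positive grid overlap: {bad}")
    w["wnorm"] = w["weight"] / w.groupby("county_id")["weight"].transform("sum")
    merged = w.merge(grid_deltas, on="cell", how="inner")
    missing = set(overlaps["county_id"]) - set(merged["county_id"])
    if missing:
        raise ValueError(f"counties whose cells carry no model values: {sorted(missing)}")
    merged["contrib"] = merged["wnorm"] * merged["delta_t"]
    out = (
        merged.groupby(["model", "county_id"], as_index=False)["contrib"]
        .sum()
        .rename(columns={"contrib": "delta_t"})
    )
    return out


def build_delta_paths(
    county_deltas: pd.DataFrame,
    base_year: int,
    end_year: int,
    ramp: str = "linear",
) -> pd.DataFrame:
    """Expand end-of-horizon county warming into per-year paths.

    ``county_deltas``: columns model, county_id, delta_t (warming at the end
    of the horizon).  ``ramp="linear"`` interpolates from 0 at ``base_year``
    to delta_t at ``end_year``; ``ramp="step"`` applies the full delta_t to
    every year after the base year.  The base-year value is always 0.
    """
    if end_year <= base_year:
        raise ValueError("end_year must be after base_year")
    if ramp not in ("linear", "step"):
        raise ValueError("ramp must be 'linear' or 'step'")
    years = np.arange(base_year, end_year + 1)
    span = end_year - base_year
    frac = (years - base_year) / span if ramp == "linear" else (years > base_year) * 1.0
    base = county_deltas.loc[:, ["model", "county_id", "delta_t"]]
    reps = base.loc[base.index.repeat(len(years))].reset_index(drop=True)
    reps["year"] = np.tile(years, len(base))
    reps["delta_t"] = reps["delta_t"].to_numpy() * np.tile(frac, len(base))
    return reps


def excess_deaths(
    pop_paths: pd.DataFrame,
    delta_paths: pd.DataFrame,
    beta: float,
    rate_scale: float = RATE_SCALE,
    months_per_year_factor: float = 12.0,
) -> pd.DataFrame:
    """Cumulative national excess deaths for one warming path.

    ``beta`` is the net monthly death-rate change per 1C in rate units of
    deaths per ``rate_scale`` person-months; the per-year excess per county
    is pop_ct * dT_ct * (beta / rate_scale) * months_per_year_factor.
    Returns columns year, excess, cumulative.
    """
    merged = delta_paths.merge(pop_paths, on=["county_id", "year"], how="inner")
    if merged.empty:
        raise ValueError("no overlap between delta paths and population paths")
    merged["excess"] = (
        merged["population"]
        * merged["delta_t"]
        * (beta / rate_scale)
        * months_per_year_factor
    )
    by_year = merged.groupby("year", as_index=False)["excess"].sum()
    by_year["cumulative"] = by_year["excess"].cumsum()
    return by_year


@dataclass
class ProjectionEnsemble:
    """B x M Monte Carlo cumulative excess-death trajectories."""

    years: np.ndarray
    trajectories: np.ndarray  # (B*M, n_years) cumulative series
    n_boot: int
    n_models: int
    betas: np.ndarray  # (B,) bootstrap net-effect draws

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.trajectories, [2.5, 25, 50, 75, 97.5], axis=0)
        return pd.DataFrame(
            {
                "year": self.years,
                "median": q[2],
                "q2.5": q[0],
                "q25": q[1],
                "q75": q[3],
                "q97.5": q[4],
            }
        )


def bootstrap_net_betas(
    panel: pd.DataFrame,
    fe_spec: FESpec,
    lag_spec: LagSpec,
    n_boot: int,
    seed: int,
    max_retries: int = 5,
) -> np.ndarray:
    """County-level cluster bootstrap of the net temperature effect.

    Counties are resampled with replacement, keeping each resampled
    county's full time series (under a fresh county id so repeated draws
    stay distinct clusters and FE cells); the displacement model is refit
    and the net (current + previous month) coefficient recorded.  A failed
    refit is redrawn up to ``max_retries`` times, with a logged tally.
    """
    rng = np.random.default_rng(seed)
    counties = np.array(sorted(panel["county_id"].unique()))
    by_county = {c: g for c, g in panel.groupby("county_id")}
    betas = np.empty(n_boot)
    n_retried = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            draw = rng.choice(counties, size=len(counties), replace=True)
            parts = []
            for j, c in enumerate(draw):
                g = by_county[c].copy()
                g["county_id"] = f"B{j:05d}"
                parts.append(g)
            boot = pd.concat(parts, ignore_index=True)
            try:
                res = fit_displacement(boot, lag_spec, fe_spec)
                betas[b] = net_effect(res, lag_spec).estimate
                break
            except Exception as exc:  # noqa: BLE001 - resample and retry
                n_retried += 1
                if attempt == max_retries:
                    raise RuntimeError(
                        f"bootstrap draw failed {max_retries + 1} times: {exc}"
                    ) from exc
    if n_retried:
        logger.info("redrew %d failed bootstrap refits", n_retried)
    return betas


def monte_carlo(
    panel: pd.DataFrame,
    fe_spec: FESpec,
    lag_spec: LagSpec,
    county_deltas: pd.DataFrame,
    pop_paths: pd.DataFrame,
    n_boot: int,
    seed: int,
    base_year: int | None = None,
    end_year: int | None = None,
    ramp: str = "linear",
    rate_scale: float = RATE_SCALE,
    months_per_year_factor: float = 12.0,
) -> ProjectionEnsemble:
    """Full uncertainty propagation: B bootstrap betas x M model paths.

    Each of the B net-effect draws is crossed with each climate model's
    county warming path, giving exactly B*M cumulative trajectories over
    the projection horizon (inferred from ``pop_paths`` unless given).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    models = sorted(county_deltas["model"].unique())
    if not models:
        raise ValueError("no climate models provided")
    base_year = int(pop_paths["year"].min()) if base_year is None else base_year
    end_year = int(pop_paths["year"].max()) if end_year is None else end_year

    betas = bootstrap_net_betas(panel, fe_spec, lag_spec, n_boot, seed)

    paths = build_delta_paths(county_deltas, base_year, end_year, ramp)
    years = np.arange(base_year, end_year + 1)
    # per-model cumulative trajectory at beta = 1, then scale by each draw
    unit = np.empty((len(models), len(years)))
    for mi, m in enumerate(models):
        sub = paths[paths["model"] == m]
        series = excess_deaths(pop_paths, sub, 1.0, rate_scale,
                               months_per_year_factor)
        series = series.set_index("year").reindex(years)
        unit[mi] = series["cumulative"].to_numpy()
    traj = (betas[:, None, None] * unit[None, :, :]).reshape(-1, len(years))
    return ProjectionEnsemble(
        years=years,
        trajectories=traj,
        n_boot=n_boot,
        n_models=len(models),
        betas=betas,
    )
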