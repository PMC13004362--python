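"""Synthetic county-month panels, station networks, climate-model warming
fields and population paths with fully known data-generating processes.

The panel generator produces a balanced county x month table whose outcome is
a police-violence death rate built from a known temperature response (linear,
natural-cubic-spline, or two-regime piecewise), optional lagged temperature
effects, a linear precipitation effect, additive county-month and state-year
fixed effects, and Gaussian noise:

    y = f(temp_m) + sum_L gamma_L temp_{m-L} + beta_p precip + d_im + a_st + eps

Rates are expressed as deaths per 10,000,000 person-months so that realistic
effect sizes are order one.  County-month intercepts can be drawn with a
stated correlation rho to the cell's mean temperature (``confounded=True``),
which biases pooled OLS while leaving the within estimator consistent — the
contrast every downstream test relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

#: rate denominator: death rates are deaths per this many person-months
RATE_SCALE = 10_000_000


# ---------------------------------------------------------------------------
# response-shape truths


@dataclass(frozen=True)
class SplineResponse:
    """Natural-cubic temperature response through ``values`` at ``knots``,
    linear beyond the boundary knots (zero second derivative outside)."""

    knots: tuple
    values: tuple

    def __call__(self, temp):
        knots = np.asarray(self.knots, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        cs = CubicSpline(knots, vals, bc_type="natural")
        t = np.asarray(temp, dtype=float)
        out = cs(np.clip(t, knots[0], knots[-1]))
        lo, hi = knots[0], knots[-1]
        dlo, dhi = float(cs(lo, 1)), float(cs(hi, 1))
        out = np.where(t < lo, vals[0] + dlo * (t - lo), out)
        out = np.where(t > hi, vals[-1] + dhi * (t - hi), out)
        return out


@dataclass(frozen=True)
class PiecewiseResponse:
    """Two-regime linear response: slope_low below the threshold,
    slope_high above (continuous at the threshold)."""

    threshold: float
    slope_low: float
    slope_high: float

    def __call__(self, temp):
        t = np.asarray(temp, dtype=float)
        return np.where(
            t <= self.threshold,
            self.slope_low * t,
            self.slope_low * self.threshold
            + self.slope_high * (t - self.threshold),
        )


@dataclass
class PanelDGPConfig:
    """Parameters of the county-month panel data-generating process.

    Defaults mimic a CONUS-scale monthly panel: 100 counties in 10 states
    over 10 years, a seasonal temperature cycle with year-to-year noise, and
    a temperature effect of 1 rate unit (deaths per 10^7 person-months) per
    degree C.
    """

    n_counties: int = 100
    n_states: int = 10
    years: tuple = (2013, 2022)
    beta_temp: float = 1.0
    beta_precip: float = -0.02
    response_shape: object = "linear"  # "linear" | SplineResponse | PiecewiseResponse
    lag_effects: tuple = ()  # ((lag, coefficient), ...)
    fe_sd_county_month: float = 5.0
    fe_sd_state_year: float = 2.0
    noise_sd: float = 10.0
    base_rate: float = 60.0
    population_range: tuple = (50_000.0, 5_000_000.0)
    temp_base_range: tuple = (2.0, 18.0)
    temp_seasonal_amplitude: float = 10.0
    temp_noise_sd: float = 2.0
    precip_mean: float = 80.0
    precip_sd: float = 40.0
    confounded: bool = False
    confound_rho: float = 0.5
    poisson_deaths: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_counties < 1:
            raise ValueError("n_counties must be positive")
        if self.n_states < 1 or self.n_states > self.n_counties:
            raise ValueError("need 1 <= n_states <= n_counties")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("years must be an inclusive (start, end) range")
        if self.fe_sd_state_year > 0 and y1 - y0 + 1 < 2:
            raise ValueError("state-year effects require a span of >= 2 years")
        for name in ("fe_sd_county_month", "fe_sd_state_year", "noise_sd",
                     "temp_noise_sd", "precip_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        max_lag = max((lag for lag, _ in self.lag_effects), default=0)
        n_months = (y1 - y0 + 1) * 12
        if n_months < max_lag + 1:
            raise ValueError("year range shorter than the lag window + 1 month")
        if not -1 <= self.confound_rho <= 1:
            raise ValueError("confound_rho must lie in [-1, 1]")


def _response_fn(config: PanelDGPConfig):
    if config.response_shape == "linear":
        beta = config.beta_temp
        return lambda t: beta * np.asarray(t, dtype=float)
    if callable(config.response_shape):
        return config.response_shape
    raise ValueError(f"unknown response_shape: {config.response_shape!r}")


def generate_panel(config: PanelDGPConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a balanced county-month panel.

    Returns the panel (one row per county, year, month) and a ``truth``
    record holding every generating coefficient, for parameter-recovery
    assertions downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    nc, ns = config.n_counties, config.n_states

    county_ids = np.array([f"C{i:04d}" for i in range(nc)])
    state_of_county = np.arange(nc) % ns  # round-robin assignment
    state_ids = np.array([f"S{s:02d}" for s in range(ns)])

    lo, hi = config.population_range
    population = np.exp(rng.uniform(np.log(lo), np.log(hi), size=nc))

    base_temp = rng.uniform(*config.temp_base_range, size=nc)

    # temperatures on an extended month axis so lags/leads stay in-sample
    lags = [lag for lag, _ in config.lag_effects]
    pad_before = max([0] + [l for l in lags if l > 0])
    pad_after = max([0] + [-l for l in lags if l < 0])
    months_axis = np.arange(-pad_before, n_years * 12 + pad_after)  # 0 = Jan y0
    month_of = ((months_axis % 12) + 12) % 12 + 1  # calendar month 1..12
    seasonal = config.temp_seasonal_amplitude * np.cos(
        2 * np.pi * (month_of - 7) / 12.0
    )
    temp_ext = (
        base_temp[:, None]
        + seasonal[None, :]
        + rng.normal(0.0, config.temp_noise_sd, size=(nc, len(months_axis)))
    )

    core = slice(pad_before, pad_before + n_years * 12)
    temp = temp_ext[:, core]  # (nc, T)
    T = n_years * 12

    precip = np.clip(
        rng.normal(config.precip_mean, config.precip_sd, size=(nc, T)), 0.0, None
    )

    # county-month fixed effects, optionally correlated with cell mean temp
    cell_mean_temp = base_temp[:, None] + seasonal[None, core][
        :, :12
    ]  # (nc, 12): deterministic part, identical across years
    z = rng.normal(size=(nc, 12))
    if config.confounded and config.fe_sd_county_month > 0:
        mu = cell_mean_temp - cell_mean_temp.mean()
        sd = mu.std()
        zt = mu / sd if sd > 0 else np.zeros_like(mu)
        rho = config.confound_rho
        fe_cm = config.fe_sd_county_month * (rho * zt + np.sqrt(1 - rho**2) * z)
    else:
        fe_cm = config.fe_sd_county_month * z

    fe_sy = config.fe_sd_state_year * rng.normal(size=(ns, n_years))

    f = _response_fn(config)
    rate = config.base_rate + f(temp) + config.beta_precip * precip
    for lag, coef in config.lag_effects:
        shifted = temp_ext[:, pad_before - lag : pad_before - lag + T]
        rate = rate + coef * shifted

    month_idx = np.tile(np.arange(12), n_years)  # calendar month - 1 per column
    year_idx = np.repeat(np.arange(n_years), 12)
    rate = rate + fe_cm[:, month_idx] + fe_sy[state_of_county][:, year_idx]
    rate = rate + rng.normal(0.0, config.noise_sd, size=(nc, T))

    panel = pd.DataFrame(
        {
            "county_id": np.repeat(county_ids, T),
            "state_id": np.repeat(state_ids[state_of_county], T),
            "year": np.tile(y0 + year_idx, nc),
            "month": np.tile(month_idx + 1, nc),
            "population": np.repeat(population, T),
            "temp": temp.ravel(),
            "precip": precip.ravel(),
        }
    )

    if config.poisson_deaths:
        lam = np.clip(rate.ravel(), 0.0, None) * panel["population"].to_numpy() / RATE_SCALE
        deaths = rng.poisson(lam)
        panel["deaths"] = deaths
        panel["death_rate"] = deaths / panel["population"] * RATE_SCALE
    else:
        panel["death_rate"] = rate.ravel()

    truth = {
        "beta_temp": config.beta_temp,
        "beta_precip": config.beta_precip,
        "response_shape": config.response_shape,
        "lag_effects": dict(config.lag_effects),
        "fe_county_month_sd": config.fe_sd_county_month,
        "fe_state_year_sd": config.fe_sd_state_year,
        "noise_sd": config.noise_sd,
        "rate_scale": RATE_SCALE,
        "seed": config.seed,
    }
    return panel, truth


# ---------------------------------------------------------------------------
# station networks


def generate_station_network(
    n_stations: int,
    bbox: tuple,
    field_fn,
    seed: int = 0,
    dates=None,
    precip_field_fn=None,
) -> pd.DataFrame:
    """Random stations inside ``bbox = (lat_min, lat_max, lon_min, lon_max)``
    with values sampled from a known smooth field ``field_fn(lat, lon)``.

    With ``dates`` (an iterable of datelike values), emits one row per
    station-date with ``temp`` from ``field_fn`` and ``precip`` from
    ``precip_field_fn`` (zero when omitted); otherwise one row per station
    with a single ``value`` column.
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    lat_min, lat_max, lon_min, lon_max = bbox
    if lat_max <= lat_min or lon_max <= lon_min:
        raise ValueError("empty bounding box")
    rng = np.random.default_rng(seed)
    lat = rng.uniform(lat_min, lat_max, size=n_stations)
    lon = rng.uniform(lon_min, lon_max, size=n_stations)
    ids = [f"ST{i:04d}" for i in range(n_stations)]
    if dates is None:
        return pd.DataFrame(
            {"station_id": ids, "lat": lat, "lon": lon, "value": field_fn(lat, lon)}
        )
    dates = pd.to_datetime(pd.Index(dates))
    nd = len(dates)
    temp = np.tile(np.asarray(field_fn(lat, lon), dtype=float), nd)
    if precip_field_fn is None:
        precip = np.zeros(n_stations * nd)
    else:
        precip = np.tile(np.asarray(precip_field_fn(lat, lon), dtype=float), nd)
    return pd.DataFrame(
        {
            "station_id": list(ids) * nd,
            "lat": np.tile(lat, nd),
            "lon": np.tile(lon, nd),
            "date": np.repeat(dates.values, n_stations),
            "temp": temp,
            "precip": precip,
        }
    )


# ---------------------------------------------------------------------------
# climate-model warming fields and population paths


def generate_climate_models(
    n_models: int,
    counties,
    delta_mean: float,
    delta_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-model, per-county end-of-horizon warming (future minus baseline
    period mean temperature), drawn Normal(delta_mean, delta_sd)."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if delta_sd < 0:
        raise ValueError("delta_sd must be >= 0")
    counties = list(counties)
    rng = np.random.default_rng(seed)
    models = [f"GCM{m:02d}" for m in range(n_models)]
    delta = rng.normal(delta_mean, delta_sd, size=(n_models, len(counties)))
    return pd.DataFrame(
        {
            "model": np.repeat(models, len(counties)),
            "county_id": counties * n_models,
            "delta_t": delta.ravel(),
        }
    )


def generate_population_paths(
    counties, start_year: int, end_year: int, growth_rate: float = 0.005
) -> pd.DataFrame:
    """Geometric county population paths:
    pop_ct = pop_c0 * (1 + growth_rate)^(t - start_year).

    ``counties`` maps county id -> base-year population (dict or a frame
    with ``county_id``/``population`` columns).
    """
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    if growth_rate <= -1:
        raise ValueError("growth_rate must be > -1")
    if isinstance(counties, pd.DataFrame):
        base = dict(zip(counties["county_id"], counties["population"]))
    else:
        base = dict(counties)
    years = np.arange(start_year, end_year + 1)
    rows = []
    for cid, p0 in base.items():
        rows.append(
            pd.DataFrame(
                {
                    "county_id": cid,
                    "year": years,
                    "population": float(p0) * (1 + growth_rate) ** (years - start_year),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
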