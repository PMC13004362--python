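"""Inverse-distance-weighted interpolation of station meteorology to county
centroids, and aggregation of the interpolated daily values into the monthly
temperature and precipitation covariates of the county-month panel.

Distances are great-circle (haversine); IDW weights are d^(-power) over the
k nearest stations, so the interpolant is a convex combination of station
values and reproduces a station's value exactly at its own location.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("heatfe.spatial_interp")

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometres between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def idw(points, target, power: float = 2.0, k_neighbors: int | None = None) -> float:
    """Inverse-distance-weighted value at ``target = (lat, lon)``.

    ``points`` is an iterable of (lat, lon, value).  Weights are
    d^(-power) over the ``k_neighbors`` nearest points (all points when
    ``None``).  A station coincident with the target returns that station's
    value exactly; several coincident stations must agree.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    pts = [(la, lo, v) for la, lo, v in points if np.isfinite(v)]
    if not pts:
        raise ValueError("no finite station values to interpolate from")
    lat = np.array([p[0] for p in pts])
    lon = np.array([p[1] for p in pts])
    val = np.array([p[2] for p in pts])
    d = haversine_km(lat, lon, target[0], target[1])

    zero = d == 0.0
    if np.any(zero):
        vals_here = np.unique(val[zero])
        if len(vals_here) > 1:
            idx = np.flatnonzero(zero)
            raise ValueError(
                f"coincident stations at target with conflicting values: "
                f"indices {idx.tolist()}, values {val[zero].tolist()}"
            )
        return float(vals_here[0])

    if k_neighbors is not None:
        k = min(int(k_neighbors), len(d))
        keep = np.argsort(d, kind="stable")[:k]
        d, val = d[keep], val[keep]
    w = d ** (-float(power))
    return float(np.sum(w * val) / np.sum(w))


def _interp_grid(st_lat, st_lon, values, tg_lat, tg_lon, power, k):
    """Vectorised IDW of one station snapshot onto many targets.

    values: (n_stations,) ; returns (n_targets,)
    """
    d = haversine_km(
        st_lat[None, :], st_lon[None, :], tg_lat[:, None], tg_lon[:, None]
    )  # (n_targets, n_stations)
    out = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        di, vi = d[i], values
        zero = di == 0.0
        if np.any(zero):
            vals_here = np.unique(vi[zero])
            if len(vals_here) > 1:
                raise ValueError("coincident stations with conflicting values")
            out[i] = vals_here[0]
            continue
        if k is not None and k < len(di):
            keep = np.argsort(di, kind="stable")[:k]
            di, vi = di[keep], vi[keep]
        w = di ** (-float(power))
        out[i] = np.sum(w * vi) / np.sum(w)
    return out


def build_weather_panel(
    stations: pd.DataFrame,
    centroids: pd.DataFrame,
    power: float = 2.0,
    k_neighbors: int | None = None,
    precip_agg: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Interpolate daily station observations to county centroids and
    aggregate to county-month covariates.

    Parameters
    ----------
    stations : frame with station_id, lat, lon, date, temp, precip
    centroids : frame with county_id, lat, lon
    precip_agg : "mean" (default) or "sum"
        Monthly precipitation as the mean of daily values (the convention
        followed here for symmetry with temperature) or as the monthly total.

    Returns
    -------
    (panel, report)
        ``panel``: county_id, year, month, temp, precip — months with zero
        daily records are absent, never zero-filled.  ``report`` lists
        counties excluded for having no reachable station, and row counts.
    """
    if precip_agg not in ("mean", "sum"):
        raise ValueError("precip_agg must be 'mean' or 'sum'")
    req = {"station_id", "lat", "lon", "date", "temp", "precip"}
    if not req.issubset(stations.columns):
        raise ValueError(f"stations table missing columns: {req - set(stations.columns)}")
    bad_lat = stations["lat"].abs() > 90
    bad_lon = stations["lon"].abs() > 180
    if bad_lat.any() or bad_lon.any():
        raise ValueError("station coordinates outside [-90,90] x [-180,180]")

    cent = centroids.reset_index(drop=True)
    tg_lat = cent["lat"].to_numpy(dtype=float)
    tg_lon = cent["lon"].to_numpy(dtype=float)

    daily = []
    stations = stations.copy()
    stations["date"] = pd.to_datetime(stations["date"])
    for date, snap in stations.groupby("date"):
        snap = snap.dropna(subset=["temp"])
        if snap.empty:
            continue
        la = snap["lat"].to_numpy(dtype=float)
        lo = snap["lon"].to_numpy(dtype=float)
        t = _interp_grid(la, lo, snap["temp"].to_numpy(dtype=float),
                         tg_lat, tg_lon, power, k_neighbors)
        p = _interp_grid(la, lo, snap["precip"].to_numpy(dtype=float),
                         tg_lat, tg_lon, power, k_neighbors)
        daily.append(
            pd.DataFrame(
                {
                    "county_id": cent["county_id"],
                    "year": date.year,
                    "month": date.month,
                    "temp": t,
                    "precip": p,
                }
            )
        )
    if not daily:
        raise ValueError("no usable daily station records")
    alldays = pd.concat(daily, ignore_index=True)
    agg = {"temp": "mean", "precip": precip_agg}
    panel = (
        alldays.groupby(["county_id", "year", "month"], as_index=False)
        .agg(agg)
        .sort_values(["county_id", "year", "month"])
        .reset_index(drop=True)
    )

    covered = set(panel["county_id"])
    excluded = [c for c in cent["county_id"] if c not in covered]
    report = {
        "n_counties": len(cent),
        "n_excluded_no_station": len(excluded),
        "excluded_counties": excluded,
        "n_county_months": len(panel),
    }
    if excluded:
        logger.warning("counties with no reachable station: %s", excluded)
    return panel, report
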