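"""Nonlinear temperature bases, AIC-based model selection, and the
exposure-response curve anchored at a reference temperature.

Candidate shapes for the temperature term f(temp):

* ``linear`` — a single slope;
* ``ncs3`` — natural cubic spline with knots at 0, 10, 20 C;
* ``ncs7`` — natural cubic spline with 7 knots evenly spaced on [-17, 33] C;
* ``polynomial`` — raw polynomial of a given degree (default 3);
* ``bspline`` — cubic B-spline with the ncs3 interior knots and boundary
  knots at the sample range.

Natural splines use the textbook naturalized truncated-power basis: with
knots x1 < ... < xK the columns are x and d_k(x) - d_{K-1}(x) for
k = 1..K-2, where d_k(x) = [(x-x_k)_+^3 - (x-x_K)_+^3] / (x_K - x_k).
This spans exactly the natural cubic splines on those knots (linear beyond
the boundary knots) and yields K-1 columns once the intercept is absorbed
by the fixed effects.

The fitted curve is reported relative to the expected rate at the reference
temperature (10 C by default): effect(T) = b(T)'g - b(ref)'g, with pointwise
delta-method variance (b(T)-b(ref))' V (b(T)-b(ref)) from the
cluster-robust covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .panel_core import FEFitResult, FESpec, Z95, fit

logger = logging.getLogger("heatfe.exposure_response")

NCS3_KNOTS = (0.0, 10.0, 20.0)
NCS7_KNOTS = tuple(np.linspace(-17.0, 33.0, 7))


@dataclass(frozen=True)
class BasisSpec:
    """Temperature-basis specification.

    kind : {"linear", "ncs3", "ncs7", "ncs", "polynomial", "bspline"}
    knots : knot locations in C (used by ncs/bspline kinds; defaults above)
    degree : polynomial degree (polynomial kind only)
    reference_temperature : anchor of the response curve, C
    """

    kind: str = "ncs3"
    knots: tuple = ()
    degree: int = 3
    reference_temperature: float = 10.0

    def resolved_knots(self) -> tuple:
        if self.knots:
            k = tuple(float(x) for x in self.knots)
        elif self.kind == "ncs7":
            k = NCS7_KNOTS
        else:
            k = NCS3_KNOTS
        if any(b <= a for a, b in zip(k, k[1:])):
            raise ValueError("knots must be strictly increasing")
        return k

    def __post_init__(self):
        if self.kind not in ("linear", "ncs3", "ncs7", "ncs", "polynomial", "bspline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def n_params(self, n_sample: int | None = None) -> int:
        if self.kind == "linear":
            return 1
        if self.kind in ("ncs", "ncs3", "ncs7"):
            return len(self.resolved_knots()) - 1
        if self.kind == "polynomial":
            return self.degree
        return len(self.resolved_knots()) + 2  # cubic bspline minus dropped col


def _natural_spline_columns(x: np.ndarray, knots) -> np.ndarray:
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    xK, xKm1 = knots[-1], knots[-2]

    def d(xi, xk):
        return (np.clip(x - xk, 0, None) ** 3 - np.clip(x - xK, 0, None) ** 3) / (
            xK - xk
        )

    cols = [x]
    dlast = d(x, xKm1)
    for k in range(K - 2):
        cols.append(d(x, knots[k]) - dlast)
    return np.column_stack(cols)


def build_basis(temps, spec: BasisSpec, allow_degenerate: bool = False) -> pd.DataFrame:
    """Design columns for f(temp) at the given temperatures.

    Column counts: 1 (linear), #knots-1 (natural splines), degree
    (polynomial), #interior_knots+2 (cubic B-spline after dropping one
    column of the partition of unity, which the fixed effects absorb).

    ``allow_degenerate`` skips the constant-input check — appropriate when
    evaluating an already-fitted basis on an arbitrary grid rather than
    building an estimation design.
    """
    x = np.asarray(temps, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("temperatures must be finite")
    if x.size and np.ptp(x) == 0 and not allow_degenerate:
        raise ValueError("all temperatures identical: basis is degenerate")

    if spec.kind == "linear":
        return pd.DataFrame({"temp": x})
    if spec.kind in ("ncs", "ncs3", "ncs7"):
        knots = spec.resolved_knots()
        if len(knots) < 3:
            raise ValueError("natural splines need at least 3 knots")
        M = _natural_spline_columns(x, knots)
        names = ["temp"] + [f"{spec.kind}_{i}" for i in range(1, M.shape[1])]
        return pd.DataFrame(M, columns=names)
    if spec.kind == "polynomial":
        return pd.DataFrame(
            {("temp" if p == 1 else f"temp_pow{p}"): x**p
             for p in range(1, spec.degree + 1)}
        )
    # bspline: cubic, interior knots from spec, boundary at sample range
    interior = np.asarray(spec.resolved_knots(), dtype=float)
    lo = min(x.min(), interior[0] - 1.0)
    hi = max(x.max(), interior[-1] + 1.0)
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    M = BSpline.design_matrix(np.clip(x, lo, hi), t, k=3).toarray()
    M = M[:, 1:]  # drop one partition-of-unity column (absorbed intercept)
    return pd.DataFrame(M, columns=[f"bs_{i}" for i in range(M.shape[1])])


def fit_basis(
    panel: pd.DataFrame,
    basis: BasisSpec,
    fe_spec: FESpec,
    temp_col: str = "temp",
) -> tuple[FEFitResult, list]:
    """Fit the FE model with the given temperature basis.

    ``fe_spec.regressors`` lists the linear controls (precipitation terms);
    the basis columns are generated from ``temp_col`` and prepended.
    Returns the fit and the basis column names.
    """
    B = build_basis(panel[temp_col].to_numpy(), basis)
    basis_cols = list(B.columns)
    work = panel.copy()
    for c in basis_cols:
        work[c] = B[c].to_numpy()
    controls = [c for c in fe_spec.regressors if c not in basis_cols]
    spec = replace(fe_spec, regressors=basis_cols + controls)
    return fit(work, spec), basis_cols


def select_model(
    panel: pd.DataFrame,
    candidates: list,
    fe_spec: FESpec,
    temp_col: str = "temp",
) -> tuple[BasisSpec, pd.DataFrame]:
    """Fit every candidate basis under identical FE / weights / clustering
    and return the AIC winner plus the full comparison table.

    Ties (AIC equal within 1e-9) break toward fewer parameters, then listing
    order.  Candidates that fail to fit are recorded with status "failed"
    and excluded from the argmin.
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    rows = []
    fits = {}
    for i, cand in enumerate(candidates):
        try:
            res, basis_cols = fit_basis(panel, cand, fe_spec, temp_col)
            rows.append(
                {
                    "kind": cand.kind,
                    "n_params": len(basis_cols),
                    "aic": res.aic,
                    "status": "ok",
                }
            )
            fits[i] = res
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            logger.warning("candidate %s failed to fit: %s", cand.kind, exc)
            rows.append(
                {"kind": cand.kind, "n_params": np.nan, "aic": np.nan,
                 "status": f"failed: {exc}"}
            )
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("every candidate basis failed to fit")
    if len(ok) < len(table):
        logger.warning("%d candidate(s) failed and were excluded from selection",
                       len(table) - len(ok))
    best_aic = ok["aic"].min()
    near = ok[np.isclose(ok["aic"], best_aic, rtol=0, atol=1e-9)]
    best_idx = int(near.sort_values("n_params", kind="stable").index[0])
    return candidates[best_idx], table


@dataclass
class ResponseCurve:
    """Temperature-response curve relative to the reference temperature."""

    temperature: np.ndarray
    effect: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    extrapolated: np.ndarray  # bool per grid point
    frequency: np.ndarray  # share of sample temps in the bin around each point
    reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temp": self.temperature,
                "effect": self.effect,
                "ci_low": self.lower,
                "ci_high": self.upper,
                "extrapolated": self.extrapolated,
                "freq": self.frequency,
            }
        )


def response_curve(
    result: FEFitResult,
    basis: BasisSpec,
    grid,
    reference: float | None = None,
    sample_temps=None,
) -> ResponseCurve:
    """Exposure-response curve from a fitted basis.

    effect(T) = b(T)'g - b(ref)'g with 95% pointwise bounds at
    +/- 1.96 * SE from the delta method.  Grid points outside the observed
    temperature range (when ``sample_temps`` is given) are flagged as
    extrapolation, not dropped.
    """
    ref = basis.reference_temperature if reference is None else float(reference)
    grid = np.asarray(grid, dtype=float)

    # evaluate basis on grid plus reference in one call so sample-dependent
    # bases (bspline boundary knots) stay consistent
    if sample_temps is not None:
        anchor = np.asarray(sample_temps, dtype=float)
    else:
        anchor = grid
    full = np.concatenate([anchor, grid, [ref]])
    B = build_basis(full, basis, allow_degenerate=True)
    basis_cols = [c for c in B.columns if c in result.names]
    if len(basis_cols) != len(B.columns):
        missing = set(B.columns) - set(result.names)
        raise ValueError(f"fit lacks basis columns {sorted(missing)}")
    M = B[basis_cols].to_numpy()
    n_anchor = len(anchor)
    Bg = M[n_anchor:-1]
    Br = M[-1]

    idx = [result.names.index(c) for c in basis_cols]
    g = result.coef[idx]
    V = result.vcov[np.ix_(idx, idx)]

    D = Bg - Br[None, :]
    eff = D @ g
    var = np.einsum("ij,jk,ik->i", D, V, D)
    se = np.sqrt(np.clip(var, 0.0, None))

    if sample_temps is not None:
        lo, hi = anchor.min(), anchor.max()
        extrap = (grid < lo) | (grid > hi)
        edges = np.concatenate(
            [[-np.inf], (grid[:-1] + grid[1:]) / 2.0, [np.inf]]
        )
        counts, _ = np.histogram(anchor, bins=edges)
        freq = counts / counts.sum() if counts.sum() else np.zeros_like(grid)
        if extrap.any():
            logger.info("%d grid points outside the observed temperature range",
                        int(extrap.sum()))
    else:
        extrap = np.zeros(grid.shape, dtype=bool)
        freq = np.full(grid.shape, np.nan)

    return ResponseCurve(
        temperature=grid,
        effect=eff,
        lower=eff - Z95 * se,
        upper=eff + Z95 * se,
        extrapolated=extrap,
        frequency=freq,
        reference=ref,
    )
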