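"""Weighted two-way fixed-effects estimation with cluster-robust inference.

The estimator absorbs high-dimensional fixed effects (e.g. county-month and
state-year cells) by iterated weighted demeaning (alternating projections)
rather than by estimating dummy coefficients, then solves weighted least
squares on the demeaned data.  Coefficients are numerically identical to the
full dummy-variable WLS solution.  Standard errors come from a CR1
cluster-robust sandwich with the cluster unit (the county) chosen by the
caller; model comparison uses a Gaussian AIC computed from the weighted sum
of squared residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("heatfe.panel_core")

#: critical value used for all 95% intervals in this package
Z95 = 1.96


class ConvergenceError(RuntimeError):
    """Demeaning failed to converge within ``max_iter`` sweeps."""


class CollinearityError(ValueError):
    """The demeaned design is rank deficient (a regressor is absorbed)."""


@dataclass
class FESpec:
    """Specification of a fixed-effects regression.

    Parameters
    ----------
    response : str
        Name of the outcome column (a death rate).
    regressors : list of str
        Slope columns: the exposure basis plus any linear controls
        (precipitation terms, lags, interactions).
    fe_groups : list
        Fixed-effect dimensions; each entry is a column name or a tuple of
        column names whose combinations define the absorbed cells, e.g.
        ``[("county_id", "month"), ("state_id", "year")]``.  An empty list
        absorbs only a global intercept.
    weights : str, optional
        Column of strictly positive regression weights (population).
    cluster : str, optional
        Column defining clusters for the robust covariance (county id).
        ``None`` treats every row as its own cluster.
    demean_tol : float
        Convergence tolerance for alternating projections, relative to the
        scale of the data.
    max_iter : int
        Maximum number of demeaning sweeps.
    """

    response: str
    regressors: list = field(default_factory=list)
    fe_groups: list = field(default_factory=list)
    weights: str | None = None
    cluster: str | None = None
    demean_tol: float = 1e-10
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if not self.regressors:
            raise ValueError("at least one regressor is required")
        if self.demean_tol <= 0:
            raise ValueError("demean_tol must be > 0")


@dataclass
class FEFitResult:
    """Result of a fixed-effects fit.

    Holds slope coefficients only; absorbed fixed effects are not reported.
    ``vcov`` is the CR1 cluster-robust covariance of the slopes.
    """

    names: list
    coef: np.ndarray
    vcov: np.ndarray
    resid: np.ndarray
    ssr_w: float
    n_obs: int
    n_clusters: int
    dof_fe: int
    aic: float
    demean_iters: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def conf_int(self) -> np.ndarray:
        """95% normal confidence intervals, shape (k, 2)."""
        se = self.se
        return np.column_stack([self.coef - Z95 * se, self.coef + Z95 * se])

    def params(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names, name="coef")

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.vcov, index=self.names, columns=self.names)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        from scipy.stats import norm

        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.coef / se, np.inf)
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        sf = self.summary_frame()
        return {
            "coefficients": {
                name: {
                    "estimate": float(row["coef"]),
                    "se": float(row["se"]),
                    "p": float(row["p"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                }
                for name, row in sf.iterrows()
            },
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "dof_fe": int(self.dof_fe),
            "aic": float(self.aic),
            "ssr_weighted": float(self.ssr_w),
            "demean_iterations": int(self.demean_iters),
        }


# ---------------------------------------------------------------------------
# demeaning


def _group_codes(panel: pd.DataFrame, group) -> np.ndarray:
    """Integer codes 0..G-1 for the FE cells defined by `group` columns."""
    cols = [group] if isinstance(group, str) else list(group)
    if len(cols) == 1:
        codes, _ = pd.factorize(panel[cols[0]], sort=True)
    else:
        codes = panel.groupby(cols, sort=True).ngroup().to_numpy()
    return np.asarray(codes, dtype=np.intp)


def within_demean(
    values: np.ndarray,
    fe_codes: list,
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> tuple[np.ndarray, int]:
    """Remove weighted group means over each FE dimension by alternating
    projections (Gauss-Seidel sweeps over the dimensions).

    Parameters
    ----------
    values : (n,) or (n, p) array
        Columns to demean jointly.
    fe_codes : list of (n,) integer arrays
        Group membership codes per FE dimension.
    weights : (n,) array, optional
        Positive weights for the weighted means; defaults to ones.
    tol : float
        Sweep terminates when the largest absolute adjustment applied to any
        cell in a full sweep drops below ``tol * scale``, with ``scale`` the
        largest absolute input value.

    Returns
    -------
    (demeaned, n_sweeps)

    Raises
    ------
    ConvergenceError
        If the tolerance is not reached in ``max_iter`` sweeps; the message
        reports the last sweep's maximum adjustment.
    """
    X = np.array(values, dtype=float, copy=True)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[:, None]
    n = X.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    codes_list = [np.asarray(c, dtype=np.intp) for c in fe_codes]
    for c in codes_list:
        if c.shape[0] != n:
            raise ValueError("group codes length mismatch")
    # bincount length covers 0..max(code); codes absent from the data have
    # zero weight and are never referenced, so guard the division only
    group_w = [np.maximum(np.bincount(c, weights=w), 1e-300) for c in codes_list]

    scale = max(1.0, float(np.max(np.abs(X))) if X.size else 1.0)
    wX = np.empty_like(X)
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        for c, gw in zip(codes_list, group_w):
            np.multiply(X, w[:, None], out=wX)
            gsum = np.zeros((gw.shape[0], X.shape[1]))
            np.add.at(gsum, c, wX)
            means = gsum / gw[:, None]
            adj = means[c]
            X -= adj
            if adj.size:
                delta = max(delta, float(np.max(np.abs(adj))))
        if delta < tol * scale:
            break
    else:
        raise ConvergenceError(
            f"demeaning did not converge in {max_iter} sweeps "
            f"(last max adjustment {delta:.3e}, tol {tol * scale:.3e})"
        )
    if len(codes_list) <= 1:
        it = min(it, 1)
    return (X[:, 0] if one_dim else X), it


def absorbed_dof(fe_codes: list) -> int:
    """Rank of the absorbed fixed-effect space.

    For one dimension this is the number of cells.  For two dimensions it is
    ``G1 + G2 - C`` where ``C`` is the number of connected components of the
    bipartite graph linking dim-1 cells to dim-2 cells through observations
    (union-find).  Additional dimensions are approximated by adding
    ``G_d - 1`` each, the standard conservative count.
    """
    if not fe_codes:
        return 0
    sizes = [int(c.max()) + 1 if len(c) else 0 for c in fe_codes]
    if len(fe_codes) == 1:
        return sizes[0]
    g1, g2 = sizes[0], sizes[1]
    parent = list(range(g1 + g2))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(fe_codes[0], fe_codes[1]):
        ra, rb = find(int(a)), find(int(b) + g1)
        if ra != rb:
            parent[rb] = ra
    components = len({find(i) for i in range(g1 + g2)})
    dof = g1 + g2 - components
    for s in sizes[2:]:
        dof += s - 1
    return dof


# ---------------------------------------------------------------------------
# estimation


def fit(panel: pd.DataFrame, spec: FESpec) -> FEFitResult:
    """Fit the fixed-effects weighted least-squares model.

    Demeans the response and regressors jointly over the FE dimensions, then
    solves WLS on the demeaned data; the slope estimates equal those of the
    full dummy-variable regression.  Residuals are the demeaned-data
    residuals, i.e. the within-cell errors.

    Raises
    ------
    CollinearityError
        If the demeaned design is rank deficient; the message names the
        offending column (typically a regressor constant within FE cells).
    ValueError
        For a single cluster (cluster-robust variance unidentified).
    """
    cols = [spec.response] + list(spec.regressors)
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    data = panel[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("response/regressors contain non-finite values")
    n = data.shape[0]
    k = len(spec.regressors)

    if spec.weights is not None:
        w = panel[spec.weights].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weight column must be strictly positive")
    else:
        w = np.ones(n)

    fe_groups = spec.fe_groups if spec.fe_groups else [()]
    fe_codes = []
    for g in fe_groups:
        if g == ():  # global intercept absorbed when no FE requested
            fe_codes.append(np.zeros(n, dtype=np.intp))
        else:
            fe_codes.append(_group_codes(panel, g))

    demeaned, iters = within_demean(
        data, fe_codes, weights=w, tol=spec.demean_tol, max_iter=spec.max_iter
    )
    yd = demeaned[:, 0]
    Xd = demeaned[:, 1:]

    sw = np.sqrt(w)
    Xs = Xd * sw[:, None]
    ys = yd * sw

    # rank check on the weighted demeaned design: a column absorbed by the
    # FE has near-zero norm relative to its pre-demeaning scale
    orig_norms = np.linalg.norm(data[:, 1:] * sw[:, None], axis=0)
    orig_norms = np.where(orig_norms > 0, orig_norms, 1.0)
    norms = np.linalg.norm(Xs, axis=0)
    absorbed = norms < 1e-8 * orig_norms
    if np.any(absorbed):
        bad = spec.regressors[int(np.argmax(absorbed))]
        raise CollinearityError(
            f"regressor '{bad}' is absorbed by the fixed effects "
            "(constant within FE cells after demeaning)"
        )
    rank = np.linalg.matrix_rank(Xs / norms, tol=1e-8)
    if rank < k:
        # name the worst offender: last pivot in a pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(Xs / norms, mode="economic", pivoting=True)
        bad = spec.regressors[piv[-1]]
        raise CollinearityError(
            f"regressor '{bad}' is collinear after demeaning "
            "(a linear combination of other regressors)"
        )

    coef, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = yd - Xd @ coef
    ssr_w = float(np.sum(w * resid**2))

    dof_fe = absorbed_dof(fe_codes)

    if spec.cluster is not None:
        cluster_codes, _ = pd.factorize(panel[spec.cluster], sort=True)
        cluster_codes = np.asarray(cluster_codes, dtype=np.intp)
    else:
        cluster_codes = np.arange(n, dtype=np.intp)

    V = cluster_vcov(Xd, resid, w, cluster_codes, dof_fe=dof_fe)
    n_clusters = int(cluster_codes.max()) + 1

    if ssr_w > 0:
        aic_value = gaussian_aic(ssr_w, n, k)
    else:  # perfect fit (noiseless data): AIC undefined, flagged as -inf
        logger.warning("zero residual SSR: AIC set to -inf")
        aic_value = -np.inf

    singletons = sum(int(np.sum(np.bincount(c) == 1)) for c in fe_codes)
    if singletons:
        logger.info("retained %d singleton FE cells (zero after demeaning)", singletons)

    return FEFitResult(
        names=list(spec.regressors),
        coef=coef,
        vcov=V,
        resid=resid,
        ssr_w=ssr_w,
        n_obs=n,
        n_clusters=n_clusters,
        dof_fe=dof_fe,
        aic=aic_value,
        demean_iters=iters,
    )


def cluster_vcov(
    design: np.ndarray,
    resid: np.ndarray,
    weights: np.ndarray,
    clusters: np.ndarray,
    dof_fe: int = 0,
) -> np.ndarray:
    """CR1 cluster-robust sandwich covariance for WLS slopes.

    ``design`` is the (demeaned) regressor matrix X, ``resid`` the WLS
    residuals e.  The meat sums weighted score vectors within clusters:

        S_g = sum_{i in g} w_i x_i e_i ,   meat = sum_g S_g S_g'

    and the small-sample factor is ``G/(G-1) * (N-1)/(N-K)`` with K counting
    slope terms plus the absorbed fixed-effect degrees of freedom.  With every
    observation its own cluster this reduces to HC1.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(resid) == X.shape[1]:
        X = X.T
    n, k = X.shape
    clusters = np.asarray(clusters, dtype=np.intp)
    G = int(clusters.max()) + 1
    if G < 2:
        raise ValueError("cluster-robust variance requires at least 2 clusters")
    w = np.asarray(weights, dtype=float)
    e = np.asarray(resid, dtype=float)

    XtWX = X.T @ (X * w[:, None])
    bread = np.linalg.inv(XtWX)

    scores = X * (w * e)[:, None]
    S = np.zeros((G, k))
    np.add.at(S, clusters, scores)
    meat = S.T @ S

    K = k + dof_fe
    if n - K <= 0:
        raise ValueError(f"non-positive residual dof: n={n}, K={K}")
    factor = (G / (G - 1)) * ((n - 1) / (n - K))
    V = factor * bread @ meat @ bread
    return 0.5 * (V + V.T)


def gaussian_aic(ssr_w: float, n_obs: int, n_params: int) -> float:
    """Gaussian AIC on the weighted SSR: ``n log(SSR_w/n) + 2k``.

    ``k`` counts slope parameters only; absorbed FE degrees of freedom are
    constant across the candidate models compared here and are omitted, so
    the value is meaningful for comparison between fits on the same panel
    under the same FE structure, not as an absolute likelihood.
    """
    if ssr_w <= 0:
        raise ValueError("weighted SSR must be positive (degenerate perfect fit)")
    if n_obs <= n_params:
        raise ValueError("non-positive residual degrees of freedom")
    return float(n_obs * np.log(ssr_w / n_obs) + 2 * n_params)


def aic(result: FEFitResult) -> float:
    """AIC of a fit (recomputed from its stored weighted SSR)."""
    return gaussian_aic(result.ssr_w, result.n_obs, len(result.names))
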