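"""Heterogeneity of the temperature effect: interaction models, binned
subgroup fits, and per-category (year / state / month / climate-region)
effect decompositions.

Three complementary designs, all estimated under the same county-month and
state-year fixed effects, population weights, and county clustering as the
main model:

* interaction:  y = g1 T + g2 (T x D) + b1 P + b2 (P x D) + FE + e, with D
  a 0/1 indicator (e.g. above the population-weighted mean precipitation);
  g2 is the differential slope, g1 + g2 the slope in the D = 1 group.
* binned: the panel is subset by bins of temperature / precipitation /
  population and the linear model is fit independently in each bin.
* categorical: temperature and precipitation are fully interacted with
  category dummies (years, states, months, climate regions); the reported
  per-category slope is the base slope plus that category's interaction,
  with a delta-method SE.  The first category (sorted) is the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel_core import FEFitResult, FESpec, Z95, fit

logger = logging.getLogger("heatfe.heterogeneity")


@dataclass(frozen=True)
class ModeratorSpec:
    """How to split the panel for a heterogeneity analysis.

    kind : {"indicator", "bins", "categorical"}
    variable : column the rule applies to (ignored for categorical with an
        explicit category column)
    cuts : bin cut points (bins kind)
    threshold : "mean" (population-weighted sample mean) or a number
        (indicator kind)
    per_county : assign the rule from the county-level (time-invariant)
        value — used for population bins
    """

    kind: str
    variable: str
    cuts: tuple = ()
    threshold: object = "mean"
    per_county: bool = False

    def __post_init__(self):
        if self.kind not in ("indicator", "bins", "categorical"):
            raise ValueError(f"unknown moderator kind {self.kind!r}")
        if self.kind == "bins" and not self.cuts:
            raise ValueError("bins moderator needs cut points")


@dataclass
class SubgroupEffect:
    """One row of a subgroup table: per-1C temperature effect in a group."""

    label: str
    estimate: float | None
    se: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    p: float | None = None
    significant: bool | None = None
    flagged: str | None = None

    @staticmethod
    def from_estimate(label, est, se, n, flagged=None) -> "SubgroupEffect":
        z = est / se if se > 0 else np.inf
        p = float(2 * norm.sf(abs(z)))
        return SubgroupEffect(
            label=str(label),
            estimate=float(est),
            se=float(se),
            ci_low=float(est - Z95 * se),
            ci_high=float(est + Z95 * se),
            n=int(n),
            p=p,
            significant=bool(p < 0.05),
            flagged=flagged,
        )


def effects_to_frame(effects, mean_rate: float | None = None) -> pd.DataFrame:
    """Tidy table of subgroup effects.

    With ``mean_rate`` (the sample-mean death rate), adds columns expressing
    each effect as a percent of the mean rate alongside the raw rate units;
    both scalings are labeled because the raw scale depends on the rate
    denominator convention.
    """
    rows = []
    for e in effects:
        row = {
            "subgroup": e.label,
            "effect": e.estimate,
            "se": e.se,
            "p": e.p,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n": e.n,
            "significant": e.significant,
            "flagged": e.flagged,
        }
        if mean_rate is not None and e.estimate is not None:
            row["effect_pct_of_mean_rate"] = 100.0 * e.estimate / mean_rate
            row["ci_low_pct_of_mean_rate"] = 100.0 * e.ci_low / mean_rate
            row["ci_high_pct_of_mean_rate"] = 100.0 * e.ci_high / mean_rate
        rows.append(row)
    return pd.DataFrame(rows)


def make_indicator(
    panel: pd.DataFrame, spec: ModeratorSpec, weights: str | None = "population"
) -> np.ndarray:
    """0/1 indicator for 'variable above threshold'.

    ``threshold="mean"`` uses the population-weighted sample mean of the
    variable; ``per_county`` applies the rule to county-level means so the
    split is time-invariant within county.
    """
    v = panel[spec.variable].to_numpy(dtype=float)
    if spec.per_county:
        cm = panel.groupby("county_id")[spec.variable].transform("mean")
        v = cm.to_numpy(dtype=float)
    if spec.threshold == "mean":
        w = (
            panel[weights].to_numpy(dtype=float)
            if weights and weights in panel.columns
            else np.ones(len(panel))
        )
        thr = float(np.average(v, weights=w))
    else:
        thr = float(spec.threshold)
    return (v > thr).astype(float)


@dataclass
class InteractionResult:
    fit: FEFitResult
    gamma2: SubgroupEffect  # differential temperature slope (D=1 minus D=0)
    beta2: SubgroupEffect  # differential precipitation slope
    slope_base: SubgroupEffect  # temperature slope in the D=0 group
    slope_moderated: SubgroupEffect  # temperature slope in the D=1 group


def interaction_fit(
    panel: pd.DataFrame,
    indicator,
    fe_spec: FESpec,
    label: str = "D",
) -> InteractionResult:
    """Fit the interaction design: temp, temp x D, precip, precip x D.

    ``indicator`` is a 0/1 array (or column name).  Both levels must be
    present.  Group-specific slopes are g1 (D=0) and g1 + g2 (D=1), the
    latter with a delta-method SE.
    """
    D = (
        panel[indicator].to_numpy(dtype=float)
        if isinstance(indicator, str)
        else np.asarray(indicator, dtype=float)
    )
    levels = np.unique(D)
    if len(levels) < 2:
        raise ValueError("indicator is constant: interaction is collinear")
    if not set(levels).issubset({0.0, 1.0}):
        raise ValueError("indicator must be 0/1")
    work = panel.copy()
    work["temp_x_D"] = work["temp"].to_numpy() * D
    work["precip_x_D"] = work["precip"].to_numpy() * D
    regs = ["temp", "temp_x_D", "precip", "precip_x_D"]
    res = fit(work, replace(fe_spec, regressors=regs))

    i_t, i_td = res.names.index("temp"), res.names.index("temp_x_D")
    i_p, i_pd = res.names.index("precip"), res.names.index("precip_x_D")
    n0 = int((D == 0).sum())
    n1 = int((D == 1).sum())
    V = res.vcov
    se_mod = float(np.sqrt(V[i_t, i_t] + V[i_td, i_td] + 2 * V[i_t, i_td]))
    return InteractionResult(
        fit=res,
        gamma2=SubgroupEffect.from_estimate(
            f"{label}=1 minus {label}=0 (temp)", res.coef[i_td],
            res.se[i_td], n1
        ),
        beta2=SubgroupEffect.from_estimate(
            f"{label}=1 minus {label}=0 (precip)", res.coef[i_pd],
            res.se[i_pd], n1
        ),
        slope_base=SubgroupEffect.from_estimate(
            f"{label}=0", res.coef[i_t], res.se[i_t], n0
        ),
        slope_moderated=SubgroupEffect.from_estimate(
            f"{label}=1", res.coef[i_t] + res.coef[i_td], se_mod, n1
        ),
    )


def _bin_labels(variable: str, cuts) -> list:
    cuts = list(cuts)
    labels = [f"{variable} < {cuts[0]:g}"]
    labels += [f"{variable} {a:g}-{b:g}" for a, b in zip(cuts, cuts[1:])]
    labels.append(f"{variable} > {cuts[-1]:g}")
    return labels


def binned_fit(
    panel: pd.DataFrame,
    moderator: ModeratorSpec,
    fe_spec: FESpec,
    regressors=("temp", "precip"),
) -> list:
    """Independent linear fits within bins of one moderating variable.

    Population-style bins (``per_county=True``) are assigned from the
    county-level mean so every county sits in one bin; temperature and
    precipitation bins are assigned per row.  Empty bins are reported with
    n = 0 and no estimate; bins with fewer than 2 county clusters are
    skipped with a flag.
    """
    cuts = [float(c) for c in moderator.cuts]
    if sorted(cuts) != cuts:
        raise ValueError("cut points must be increasing")
    v = panel[moderator.variable].to_numpy(dtype=float)
    if moderator.per_county:
        v = panel.groupby("county_id")[moderator.variable].transform("mean").to_numpy()
    edges = [-np.inf] + cuts + [np.inf]
    labels = _bin_labels(moderator.variable, cuts)
    out = []
    spec = replace(fe_spec, regressors=list(regressors))
    for lo, hi, label in zip(edges, edges[1:], labels):
        mask = (v >= lo) & (v < hi)
        sub = panel[mask]
        if sub.empty:
            out.append(SubgroupEffect(label, None, None, None, None, 0,
                                      flagged="empty bin"))
            continue
        n_clusters = sub["county_id"].nunique()
        if n_clusters < 2:
            out.append(
                SubgroupEffect(label, None, None, None, None, len(sub),
                               flagged="fewer than 2 clusters")
            )
            continue
        try:
            res = fit(sub, spec)
        except Exception as exc:  # degenerate subset is a data property
            out.append(SubgroupEffect(label, None, None, None, None, len(sub),
                                      flagged=f"fit failed: {exc}"))
            continue
        i = res.names.index("temp")
        out.append(SubgroupEffect.from_estimate(label, res.coef[i], res.se[i],
                                                len(sub)))
    return out


def categorical_effects(
    panel: pd.DataFrame,
    dimension: str,
    fe_spec: FESpec,
) -> list:
    """Per-category temperature slopes from a fully interacted model.

    ``dimension`` is a column (year, state_id, month, climate_region, ...).
    The design holds main temp/precip terms plus interactions with dummies
    for every non-reference category; the reported slope for the reference
    category (first in sorted order, noted in its label) is the main effect,
    and for the others the main effect plus the interaction, with
    delta-method SEs.  Categories containing a single county cluster are
    estimated but flagged.
    """
    cats = sorted(panel[dimension].unique())
    if len(cats) < 2:
        raise ValueError("categorical effects need >= 2 categories")
    ref = cats[0]
    work = panel.copy()
    regs = ["temp", "precip"]
    for c in cats[1:]:
        d = (work[dimension] == c).astype(float).to_numpy()
        tcol, pcol = f"temp_x_{dimension}_{c}", f"precip_x_{dimension}_{c}"
        work[tcol] = work["temp"].to_numpy() * d
        work[pcol] = work["precip"].to_numpy() * d
        regs += [tcol, pcol]
    res = fit(work, replace(fe_spec, regressors=regs))

    i_t = res.names.index("temp")
    out = []
    for c in cats:
        sub = panel[panel[dimension] == c]
        n = len(sub)
        flag = None
        if sub["county_id"].nunique() < 2:
            flag = "single county cluster"
        if c == ref:
            eff = SubgroupEffect.from_estimate(
                f"{dimension}={c} (reference)", res.coef[i_t], res.se[i_t],
                n, flagged=flag
            )
        else:
            j = res.names.index(f"temp_x_{dimension}_{c}")
            est = res.coef[i_t] + res.coef[j]
            se = float(
                np.sqrt(
                    res.vcov[i_t, i_t]
                    + res.vcov[j, j]
                    + 2 * res.vcov[i_t, j]
                )
            )
            eff = SubgroupEffect.from_estimate(f"{dimension}={c}", est, se, n,
                                               flagged=flag)
        out.append(eff)
    return out
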