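"""Univariate reference analyses: linear mixed-effects and per-region t tests.

Both operate on the natural-log binding parameter only, mirroring the
conventional analysis pipeline PuMBA is benchmarked against: the LME model
has group and region as fixed effects with a random subject intercept
(REML, Wald 95% CI); t tests compare the groups independently per region
(Welch, unequal variances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["UnivariateResult", "fit_lme", "ttest_by_region"]


@dataclass(frozen=True)
class UnivariateResult:
    """Log-scale group-difference estimate from a univariate method."""

    method: str  # "lme" | "ttest"
    region: str  # region name, or "all" for the pooled LME
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    flagged: bool = False

    def __post_init__(self):
        if np.isfinite(self.estimate) and not (
            self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12
        ):
            raise ValueError("estimate must lie inside its confidence interval")


def _check_groups(table: pd.DataFrame):
    groups = sorted(pd.unique(table["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    return groups


def fit_lme(table: pd.DataFrame, binding_parameter: str) -> UnivariateResult:
    """REML linear mixed model of the log binding parameter on group and
    region (fixed) with a random subject intercept; Wald 95% CI on the group
    coefficient.  A singular random-effect fit is reported with a flag and a
    warning rather than raised."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    groups = _check_groups(table)
    if table["region"].nunique() < 2:
        # single region: region fixed effect drops out
        formula = f"{binding_parameter} ~ group"
    else:
        formula = f"{binding_parameter} ~ group + C(region)"
    df = table.copy()
    df["group"] = pd.Categorical(df["group"], categories=groups)

    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["subject"])
        try:
            fit = model.fit(reml=True)
        except Exception as exc:  # pragma: no cover - rare numerical failure
            warnings.warn(f"LME fit failed ({exc}); refitting with method='lbfgs'")
            fit = model.fit(reml=True, method="lbfgs")
            flagged = True
    if any(issubclass(w.category, (ConvergenceWarning, RuntimeWarning)) for w in caught):
        flagged = True
        warnings.warn("LME random-effect fit is singular or did not fully converge")

    term = f"group[T.{groups[1]}]"
    est = float(fit.params[term])
    se = float(fit.bse[term])
    # Wald CI with between-subject degrees of freedom: the group effect is a
    # between-subject contrast, so n_subjects - 2 (Satterthwaite's value in a
    # balanced design); plain z quantiles are anti-conservative here
    dof = max(table["subject"].nunique() - 2, 1)
    crit = stats.t.ppf(0.975, dof)
    p = float(2 * stats.t.sf(abs(est / se), dof)) if se > 0 else (0.0 if est != 0 else 1.0)
    return UnivariateResult("lme", "all", est, se, est - crit * se, est + crit * se, p, flagged)


def ttest_by_region(table: pd.DataFrame, binding_parameter: str) -> list:
    """Welch two-sample t test of the log binding parameter per region, with
    t-distribution 95% CIs.  Regions with fewer than two subjects in either
    group are skipped with a warning."""
    groups = _check_groups(table)
    results = []
    for region, sub in table.groupby("region", sort=True):
        a = sub.loc[sub["group"] == groups[1], binding_parameter].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == groups[0], binding_parameter].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"region {region!r} has fewer than 2 subjects per group; skipped")
            continue
        est = float(a.mean() - b.mean())
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        if se == 0:  # degenerate: no within-group variability
            p = 1.0 if est == 0 else 0.0
            lo = hi = est
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            ci = res.confidence_interval(0.95)
            p, lo, hi = float(res.pvalue), float(ci.low), float(ci.high)
        results.append(UnivariateResult("ttest", str(region), est, se, lo, hi, p))
    return results
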