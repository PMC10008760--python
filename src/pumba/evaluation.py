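"""Study-level evaluation metrics across simulation replicates.

For each method and condition: statistical power (or false-positive rate at
zero true difference), bias of the mean estimate, precision (mean SE),
between-replicate SD and their ratio, plus recovery of the hierarchy
correlation matrices.  Power is estimated by fitting smooth densities to the
distributions of the 95%-interval bounds across replicates and summing the
probability that the lower bound clears zero from above with the
probability that the upper bound clears it from below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import tail_probability

__all__ = [
    "StudyEvaluation",
    "estimate_power",
    "summarize_study",
    "correlation_recovery",
]


@dataclass(frozen=True)
class StudyEvaluation:
    """Per-method evaluation metrics for one study condition."""

    metrics: pd.DataFrame  # one row per method
    true_delta: float | None

    def for_method(self, method: str) -> pd.Series:
        return self.metrics.set_index("method").loc[method]


def estimate_power(ci_lows, ci_highs, null_value: float = 0.0,
                   estimator: str = "logspline") -> tuple:
    """Probability that a 95% interval excludes ``null_value``.

    Returns ``(power, (upper_tail, lower_tail))`` where the components are
    P(ci_low > null) and P(ci_high < null) under densities fitted to the
    bound distributions.  Against a true nonzero difference this is the
    power; at a true difference of zero it is the false-positive rate.
    """
    lows = np.asarray(ci_lows, dtype=float)
    highs = np.asarray(ci_highs, dtype=float)
    if lows.shape != highs.shape or lows.ndim != 1:
        raise ValueError("ci_lows and ci_highs must be 1-D and equal length")
    if np.any(lows > highs):
        raise ValueError("each ci_low must not exceed its ci_high")
    if len(lows) < 20:
        warnings.warn("fewer than 20 replicates: power estimates are unstable")
    upper = tail_probability(lows, null_value, side="above", estimator=estimator)
    lower = tail_probability(highs, null_value, side="below", estimator=estimator)
    power = float(np.clip(upper + lower, 0.0, 1.0))
    return power, (float(upper), float(lower))


def summarize_study(results: pd.DataFrame, true_delta: float | None = None,
                    estimator: str = "logspline") -> StudyEvaluation:
    """Aggregate per-replicate group-difference results into study metrics.

    ``results`` needs columns method, replicate, estimate, se, ci_low,
    ci_high; one row per method per replicate.  If a ``condition`` column is
    present it must be constant (summaries never mix conditions).
    """
    needed = {"method", "replicate", "estimate", "se", "ci_low", "ci_high"}
    missing = needed - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    if "condition" in results.columns and results["condition"].nunique() > 1:
        raise ValueError("results mix multiple conditions; summarise each separately")
    rows = []
    for method, sub in results.groupby("method", sort=True):
        if len(sub) < 2:
            raise ValueError(f"method {method!r} has fewer than 2 replicates")
        est = sub["estimate"].to_numpy(dtype=float)
        exclusion, _ = estimate_power(
            sub["ci_low"].to_numpy(dtype=float),
            sub["ci_high"].to_numpy(dtype=float),
            estimator=estimator,
        )
        sd = float(est.std(ddof=1))
        row = {
            "method": method,
            "n_replicates": len(sub),
            "mean_estimate": float(est.mean()),
            "mean_se": float(sub["se"].mean()),
            "sd_estimates": sd,
        }
        if true_delta is not None and true_delta != 0:
            row["power"] = exclusion
            row["bias"] = float(est.mean() - true_delta)
            row["bias_sd_ratio"] = abs(row["bias"]) / sd if sd > 0 else np.inf
        elif true_delta == 0:
            row["fpr"] = exclusion
            row["bias"] = float(est.mean())
            row["bias_sd_ratio"] = abs(row["bias"]) / sd if sd > 0 else np.inf
        else:
            row["exclusion_rate"] = exclusion
        rows.append(row)
    return StudyEvaluation(pd.DataFrame(rows), true_delta)


def correlation_recovery(true_corr: dict, summaries: list, hierarchy: str = "subject") -> pd.DataFrame:
    """Compare true correlation values to posterior means across replicates.

    ``true_corr`` maps ``(param_a, param_b)`` pairs to the generating
    correlation; ``summaries`` is a list of :class:`PosteriorSummary`.
    Returns one row per parameter pair with the true value and the mean and
    SD of the posterior-mean correlations across replicates.
    """
    rows = []
    for (pa, pb), true_value in true_corr.items():
        name = f"cor_{hierarchy}[{pa},{pb}]"
        alt = f"cor_{hierarchy}[{pb},{pa}]"
        vals = []
        for s in summaries:
            if name in s.table.index:
                vals.append(float(s.table.loc[name, "mean"]))
            elif alt in s.table.index:
                vals.append(float(s.table.loc[alt, "mean"]))
            else:
                raise ValueError(f"no estimated correlation for pair ({pa}, {pb})")
        vals = np.asarray(vals)
        rows.append(
            {
                "hierarchy": hierarchy,
                "pair": f"{pa},{pb}",
                "true": float(true_value),
                "mean_posterior_mean": float(vals.mean()),
                "sd_posterior_mean": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
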