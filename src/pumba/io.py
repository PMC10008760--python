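"""CSV/YAML/JSON round-tripping for every interchange schema.

All tables are long-format UTF-8 CSVs with '.' decimals.  Schemas:

* TAC CSV: subject, region, frame_start_min, frame_dur_min, value
  [, weight]
* AIF CSV: time_min, concentration
* fit-result CSV: subject, region, model, one column per log parameter,
  rss, converged, cond_number
* parameter table CSV: subject, region, group [, covariates], one column
  per log parameter
* posterior CSV: quantity, mean, sd, q2.5, q97.5, rhat, ess
* univariate results CSV: method, region, estimate, se, ci_low, ci_high,
  p_value
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import ArterialInputFunction, FrameSchedule, TimeActivityCurve
from .model import HierarchicalModelSpec
from .priors import PriorSettings

__all__ = [
    "read_tacs",
    "write_tacs",
    "read_aif",
    "write_aif",
    "write_fit_results",
    "read_parameter_table",
    "write_parameter_table",
    "write_posterior",
    "read_posterior",
    "write_univariate_results",
    "read_model_spec",
    "write_model_spec",
    "write_manifest",
]


class SchemaError(ValueError):
    """A file violated one of the interchange schemas."""


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def read_tacs(path) -> list:
    """Read a TAC CSV into a list of TimeActivityCurve (one per
    subject-region), validating timing frame by frame."""
    df = pd.read_csv(path)
    _require(df, ["subject", "region", "frame_start_min", "frame_dur_min", "value"], path)
    tacs = []
    for (subj, region), sub in df.groupby(["subject", "region"], sort=True):
        sub = sub.sort_values("frame_start_min")
        if (sub["frame_dur_min"] <= 0).any():
            row = sub.index[sub["frame_dur_min"] <= 0][0]
            raise SchemaError(f"{path}: nonpositive frame duration at row {row} "
                              f"(subject {subj}, region {region})")
        try:
            schedule = FrameSchedule(sub["frame_start_min"].to_numpy(),
                                     sub["frame_dur_min"].to_numpy())
            weights = sub["weight"].to_numpy() if "weight" in sub.columns else None
            tacs.append(TimeActivityCurve(schedule, sub["value"].to_numpy(),
                                          weights=weights,
                                          subject=str(subj), region=str(region)))
        except ValueError as exc:
            raise SchemaError(f"{path}: subject {subj}, region {region}: {exc}") from exc
    return tacs


def write_tacs(tacs, path) -> None:
    rows = []
    for tac in tacs:
        for f in range(tac.frame_schedule.n_frames):
            row = {
                "subject": tac.subject,
                "region": tac.region,
                "frame_start_min": tac.frame_schedule.start_times[f],
                "frame_dur_min": tac.frame_schedule.durations[f],
                "value": tac.values[f],
            }
            if tac.weights is not None:
                row["weight"] = tac.weights[f]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aif(path) -> ArterialInputFunction:
    df = pd.read_csv(path)
    _require(df, ["time_min", "concentration"], path)
    try:
        return ArterialInputFunction(df["time_min"].to_numpy(), df["concentration"].to_numpy())
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_aif(aif: ArterialInputFunction, path) -> None:
    pd.DataFrame({"time_min": aif.times, "concentration": aif.concentrations}).to_csv(
        path, index=False
    )


def write_fit_results(fits, tacs, path) -> None:
    """One row per fitted TAC: log-scale estimates plus fit diagnostics."""
    rows = []
    for fit, tac in zip(fits, tacs):
        rows.append(
            {
                "subject": tac.subject,
                "region": tac.region,
                "model": fit.model_id,
                **fit.estimates,
                "rss": fit.objective,
                "converged": fit.converged,
                "cond_number": fit.condition_number,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parameter_table(path, parameters=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["subject", "region"], path)
    if parameters is not None:
        _require(df, parameters, path)
        vals = df[list(parameters)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = df.index[~np.isfinite(vals).all(axis=1)][0]
            raise SchemaError(f"{path}: non-finite parameter value at row {bad}")
    return df


def write_parameter_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_posterior(summary, path) -> None:
    summary.to_frame().to_csv(path, index=False)


def read_posterior(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["quantity", "mean", "sd", "q2.5", "q97.5", "rhat", "ess"], path)
    return df.set_index("quantity")


def write_univariate_results(results, path) -> None:
    pd.DataFrame(
        [
            {
                "method": r.method,
                "region": r.region,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_model_spec(spec: HierarchicalModelSpec, path) -> None:
    doc = {
        "parameters": list(spec.parameters),
        "binding_parameter": spec.binding_parameter,
        "formulas": dict(spec.formulas),
        "region_fixed": list(spec.region_fixed),
        "priors": spec.priors.to_dict(),
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_model_spec(path) -> HierarchicalModelSpec:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return HierarchicalModelSpec(
            parameters=tuple(doc["parameters"]),
            binding_parameter=doc["binding_parameter"],
            priors=PriorSettings.from_dict(doc["priors"]),
            formulas=dict(doc.get("formulas", {})),
            region_fixed=tuple(doc.get("region_fixed", ())),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid model spec ({exc})") from exc


def write_manifest(path, seed: int, extra: dict | None = None) -> None:
    """Record seed and software versions so a run can be reproduced."""
    import emcee
    import scipy

    import pumba

    doc = {
        "seed": int(seed),
        "versions": {
            "pumba": pumba.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "emcee": emcee.__version__,
        },
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
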