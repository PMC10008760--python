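"""Generative machinery for the two simulation designs.

Parameter-level simulation draws log-scale PK parameter tables directly from
the hierarchical generative model (NLS estimation error is folded into the
residual term).  TAC-level simulation additionally pushes the drawn true
parameters through the 2TC forward model and adds frame-wise measurement
noise whose per-frame variance follows the NLS weighting model, scaled by an
error multiplier.

Both designs place a group shift ``delta`` on the log binding parameter of
the patient group, use fixed per-region offset values, and multivariate
normal subject deviations and residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import (
    ArterialInputFunction,
    CARBON11_HALFLIFE_MIN,
    FrameSchedule,
    PK2TC,
    TimeActivityCurve,
    make_default_schedule,
    make_synthetic_aif,
    simulate_tac_2tc,
)
from .profiles import TracerProfile, get_profile

__all__ = [
    "GenerativeConfig",
    "generate_parameter_dataset",
    "generate_tac_dataset",
    "make_study",
    "Study",
]

#: error multipliers examined by the TAC-simulation presets
PRESET_ERROR_MULTIPLIERS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class GenerativeConfig:
    """Study conditions for one simulation condition.

    ``n_per_group`` subjects are drawn per group (patients and controls),
    each with the profile's nine regions.  ``delta`` is the log-scale group
    difference added to the binding parameter of patients (0.1 corresponds
    to a 10.5% group difference).
    """

    profile: TracerProfile
    delta: float = 0.1
    n_per_group: int = 20
    mode: str = "parameter"  # "parameter" | "tac"
    error_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("parameter", "tac"):
            raise ValueError("mode must be 'parameter' or 'tac'")
        if self.mode == "tac" and self.profile.model_id != "2tc":
            raise ValueError("TAC-mode generation uses the 2TC forward model")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.error_multiplier < 0:
            raise ValueError("error multiplier must be nonnegative")

    @classmethod
    def preset(cls, profile_name: str, **kwargs) -> "GenerativeConfig":
        return cls(profile=get_profile(profile_name), **kwargs)


def _draw_table(cfg: GenerativeConfig, rng: np.random.Generator) -> pd.DataFrame:
    prof = cfg.profile
    m, K = prof.m, len(prof.regions)
    n = cfg.n_per_group
    subjects = [f"c{i + 1:03d}" for i in range(n)] + [f"p{i + 1:03d}" for i in range(n)]
    groups = ["Control"] * n + ["Patient"] * n

    alpha = prof.alpha_vector()
    offsets = np.stack([prof.region_offsets[p] for p in prof.parameters], axis=1)  # (K, m)
    tau = rng.multivariate_normal(np.zeros(m), prof.cov_subject(), size=2 * n)
    eps = rng.multivariate_normal(np.zeros(m), prof.cov_resid(), size=(2 * n, K))
    b = prof.parameters.index(prof.binding_parameter)

    rows = []
    for j, (subj, grp) in enumerate(zip(subjects, groups)):
        shift = np.zeros(m)
        if grp == "Patient":
            shift[b] = cfg.delta
        theta = alpha[None, :] + shift[None, :] + offsets + tau[j][None, :] + eps[j]  # (K, m)
        for k, region in enumerate(prof.regions):
            rows.append({"subject": subj, "region": region, "group": grp,
                         **{p: theta[k, i] for i, p in enumerate(prof.parameters)}})
    return pd.DataFrame(rows)


def generate_parameter_dataset(cfg: GenerativeConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a long-format log-scale PK parameter table from the generative
    model: theta = alpha + delta * 1[binding, patient] + region offset +
    subject deviation + residual."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return _draw_table(cfg, rng)


def _frame_noise_sd(curve: np.ndarray, schedule: FrameSchedule, fraction: float,
                    multiplier: float, halflife: float = CARBON11_HALFLIFE_MIN) -> np.ndarray:
    """Per-frame noise SDs following the weighting model's variance shape
    (decay-corrected activity over frame duration), scaled so the average
    relative noise is ``fraction`` at multiplier 1."""
    lam = np.log(2.0) / halflife
    c = np.maximum(np.abs(curve), 0.05 * np.abs(curve).max())
    vprof = c * np.exp(lam * schedule.mid_times) / schedule.durations
    shape = np.sqrt(vprof / vprof.mean())
    return multiplier * fraction * curve.mean() * shape


def generate_tac_dataset(
    cfg: GenerativeConfig,
    seed: int | None = None,
    aif: ArterialInputFunction | None = None,
    schedule: FrameSchedule | None = None,
):
    """Draw true 2TC parameters per subject and region, simulate noiseless
    TACs from them, and add frame-wise Gaussian measurement noise.

    Returns ``(tacs, truth)``: the noisy curves (with correctly specified
    weights attached) and the underlying true parameter table.
    """
    if cfg.mode != "tac":
        raise ValueError("config is not in TAC mode")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = _draw_table(cfg, rng)
    aif = aif if aif is not None else make_synthetic_aif()
    schedule = schedule if schedule is not None else make_default_schedule()
    prof = cfg.profile

    tacs = []
    for _, row in truth.iterrows():
        params = PK2TC(**{name[3:]: np.exp(row[name]) for name in prof.parameters})
        clean = simulate_tac_2tc(params, aif, schedule,
                                 subject=row["subject"], region=row["region"])
        base_sd = _frame_noise_sd(clean.values, schedule, prof.tac_error_fraction, 1.0)
        noisy = clean.values + cfg.error_multiplier * base_sd * rng.normal(size=len(base_sd))
        w = 1.0 / base_sd**2
        tacs.append(TimeActivityCurve(schedule, noisy, weights=w / w.mean(),
                                      subject=row["subject"], region=row["region"]))
    return tacs, truth


@dataclass(frozen=True)
class Study:
    """A seeded collection of independent replicate datasets."""

    config: GenerativeConfig
    replicates: int
    seeds: tuple

    @property
    def seed_ledger(self) -> list:
        return [{"replicate": i, "seed": int(s)} for i, s in enumerate(self.seeds)]

    def __iter__(self):
        for i, s in enumerate(self.seeds):
            if self.config.mode == "parameter":
                yield i, int(s), generate_parameter_dataset(self.config, seed=int(s))
            else:
                yield i, int(s), generate_tac_dataset(self.config, seed=int(s))

    def dataset(self, replicate: int):
        """Regenerate a single replicate from its ledger seed."""
        s = int(self.seeds[replicate])
        if self.config.mode == "parameter":
            return generate_parameter_dataset(self.config, seed=s)
        return generate_tac_dataset(self.config, seed=s)


def make_study(cfg: GenerativeConfig, replicates: int) -> Study:
    """Plan a replicated study with counter-based per-replicate seeds, so any
    replicate is individually reproducible from the master seed."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seeds = tuple(
        int(np.random.SeedSequence((cfg.seed, i)).generate_state(1)[0] % (2**31))
        for i in range(replicates)
    )
    return Study(cfg, replicates, seeds)
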