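"""Prior settings for the multivariate hierarchical model.

Intercepts get moderately informative normal priors centred on log-scale
plausible values for the tracer; covariate effects get zero-centred normal
priors; hierarchy standard deviations get zero-centred half-normal priors;
and correlation matrices get LKJ priors.  All settings are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["PriorSettings", "default_priors", "perturb_intercept_priors"]


@dataclass(frozen=True)
class PriorSettings:
    """Prior hyperparameters, everything on the natural-log parameter scale.

    Parameters
    ----------
    alpha_mean : dict
        Prior mean of each parameter's global intercept (log of a plausible
        central value for the tracer).
    alpha_sd : float
        Prior SD of the intercepts (default 0.25, i.e. roughly +/-65% on the
        natural scale at 2 SD).
    beta_sd : float
        Prior SD of covariate effects, including the group difference
        (default 0.1).
    sd_scale : float
        Half-normal scale for all hierarchy standard deviations
        (default 0.3).
    lkj_eta : float
        LKJ shape for all correlation matrices (default 2, mildly favouring
        identity).
    region_offset_sd : float
        Prior SD of per-region fixed-effect offsets; wide by default since
        regional differences in delivery and binding can be large.
    """

    alpha_mean: dict
    alpha_sd: float = 0.25
    beta_sd: float = 0.1
    sd_scale: float = 0.3
    lkj_eta: float = 2.0
    region_offset_sd: float = 5.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_mean"] = {k: float(v) for k, v in d["alpha_mean"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSettings":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "PriorSettings":
        return cls.from_dict(yaml.safe_load(text))


def default_priors(tracer_profile, **overrides) -> PriorSettings:
    """Build default priors from a tracer profile's central values.

    ``tracer_profile`` must expose ``log_central`` mapping each log-scale
    parameter name to the log of its plausible central value (a
    :class:`~pumba.profiles.TracerProfile` does).
    """
    centers = dict(tracer_profile.log_central)
    if not centers:
        raise ValueError("tracer profile provides no central values")
    return PriorSettings(alpha_mean=centers, **overrides)


def perturb_intercept_priors(
    priors: PriorSettings, magnitude: float = 0.69, seed: int = 0
) -> PriorSettings:
    """Randomly shift each intercept prior mean by +/-``magnitude`` (default
    0.69 = ln 2, i.e. halving or doubling the central value), independently
    per parameter — the prior-misspecification stress test."""
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=len(priors.alpha_mean))
    shifted = {
        name: mean + s * magnitude
        for (name, mean), s in zip(priors.alpha_mean.items(), signs)
    }
    d = priors.to_dict()
    d["alpha_mean"] = shifted
    return PriorSettings.from_dict(d)
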