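"""Compartmental forward models for PET time activity curves.

Implements the one- and two-tissue compartment models (1TC, 2TC) driven by an
arterial input function (AIF), and the simplified reference tissue model
(SRTM) driven by a reference-region curve.  Tissue curves are computed by
analytic convolution of the model impulse response function with a
piecewise-linear input, which is exact for the interpolated input and avoids
quadrature error at coarse frame schedules.

Parameterisations follow the convention of one blood-delivery parameter and
one binding parameter per model, with the remaining micro-constants derived:

* 2TC: (K1, VND, BPP, k4) with k2 = K1/VND, k3 = k4*BPP/VND,
  VT = VND + BPP, BPND = BPP/VND.
* 1TC: (K1, VT) with k2 = K1/VT.
* SRTM: (R1, k2prime, BPND) with k2 = R1*k2prime, k2a = k2/(1 + BPND).

All radioactivity concentrations are in arbitrary (but consistent) units;
times are in minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "ArterialInputFunction",
    "TimeActivityCurve",
    "PK2TC",
    "PK1TC",
    "PKSRTM",
    "make_default_schedule",
    "make_synthetic_aif",
    "simulate_tac_2tc",
    "simulate_tac_1tc",
    "simulate_tac_srtm",
    "compute_weights",
    "CARBON11_HALFLIFE_MIN",
]

#: Radioactive half-life of carbon-11 in minutes.
CARBON11_HALFLIFE_MIN = 20.4


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: start times and durations in minutes."""

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_times, dtype=float)
        dur = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "durations", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("start_times and durations must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if np.any(start[1:] < (start[:-1] + dur[:-1]) - 1e-9):
            raise ValueError("frames must not overlap")

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def n_frames(self) -> int:
        return len(self.start_times)

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        dur = np.asarray(durations, dtype=float)
        return cls(np.concatenate([[0.0], np.cumsum(dur)[:-1]]), dur)


@dataclass(frozen=True)
class ArterialInputFunction:
    """Arterial plasma concentration sampled on a time grid.

    The curve is interpreted as piecewise linear between samples and is
    forced through (0, 0); convolution with exponentials is then analytic.
    """

    times: np.ndarray
    concentrations: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t[0] != 0.0:
            raise ValueError("AIF must start at t=0 (prepend a (0, 0) sample)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("AIF concentrations must be nonnegative")
        if c[0] != 0.0:
            raise ValueError("AIF concentration at t=0 must be 0")
        if self.interpolation != "linear":
            raise ValueError(f"unsupported interpolation rule {self.interpolation!r}")

    def __call__(self, t):
        return np.interp(t, self.times, self.concentrations)


@dataclass(frozen=True)
class TimeActivityCurve:
    """One region's radioactivity concentration per frame."""

    frame_schedule: FrameSchedule
    values: np.ndarray
    weights: np.ndarray | None = None
    region: str = ""
    subject: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != self.frame_schedule.n_frames:
            raise ValueError("values length must match number of frames")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != v.shape:
                raise ValueError("weights length must match number of frames")
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("weights must be nonnegative with at least one > 0")

    def with_weights(self, weights) -> "TimeActivityCurve":
        return dataclasses.replace(self, weights=np.asarray(weights, dtype=float))


def _positive(**kwargs):
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class PK2TC:
    """Two-tissue compartment parameters: delivery K1, non-displaceable
    distribution volume VND, binding potential BPP (relative to plasma) and
    dissociation rate k4."""

    K1: float
    VND: float
    BPP: float
    k4: float

    def __post_init__(self):
        _positive(K1=self.K1, VND=self.VND, BPP=self.BPP, k4=self.k4)

    @property
    def k2(self) -> float:
        return self.K1 / self.VND

    @property
    def k3(self) -> float:
        return self.k4 * self.BPP / self.VND

    @property
    def VT(self) -> float:
        return self.VND + self.BPP

    @property
    def BPND(self) -> float:
        return self.BPP / self.VND


@dataclass(frozen=True)
class PK1TC:
    """One-tissue compartment parameters: delivery K1 and total
    distribution volume VT."""

    K1: float
    VT: float

    def __post_init__(self):
        _positive(K1=self.K1, VT=self.VT)

    @property
    def k2(self) -> float:
        return self.K1 / self.VT


@dataclass(frozen=True)
class PKSRTM:
    """Simplified reference tissue model parameters: relative delivery R1,
    reference-region efflux k2prime and binding potential BPND."""

    R1: float
    k2prime: float
    BPND: float

    def __post_init__(self):
        _positive(R1=self.R1, k2prime=self.k2prime, BPND=self.BPND)

    @property
    def k2(self) -> float:
        return self.R1 * self.k2prime

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BPND)


def exp_conv(theta: float, times: np.ndarray, conc: np.ndarray, t_eval: np.ndarray) -> np.ndarray:
    """Convolve a piecewise-linear curve with exp(-theta*t), exactly.

    Returns E(t) = integral_0^t C(s) * exp(-theta*(t-s)) ds for each t in
    ``t_eval``, where C is linear between the (times, conc) samples and zero
    before t=0.  For |theta| below 1e-12 the limit (the running integral of
    C) is returned.
    """
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    out = np.zeros_like(t_eval)
    t0s, t1s = times[:-1], times[1:]
    c0s, c1s = conc[:-1], conc[1:]
    if theta < 1e-12:
        # limit: running integral of C (exact for piecewise-linear C)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (c0s + c1s) * (t1s - t0s))])
        idx = np.clip(np.searchsorted(times, t_eval, side="right") - 1, 0, len(t0s) - 1)
        tl, cl = times[idx], conc[idx]
        g = (conc[idx + 1] - cl) / (times[idx + 1] - tl)
        dt = np.clip(t_eval - tl, 0.0, None)
        return cum[idx] + cl * dt + 0.5 * g * dt**2
    # broadcast segments x evaluation times; antiderivative
    # F(s) = exp(-theta*(t-s)) * ((c0 + g*(s-t0))/theta - g/theta^2)
    g = ((c1s - c0s) / (t1s - t0s))[:, None]
    t0c, t1c, c0c = t0s[:, None], t1s[:, None], c0s[:, None]
    te = t_eval[None, :]
    active = te > t0c
    u = np.minimum(te, t1c)
    # exponents clamped at 0 on inactive entries to avoid overflow
    e_u = np.exp(-theta * np.clip(te - u, 0.0, None))
    e_0 = np.exp(-theta * np.clip(te - t0c, 0.0, None))
    upper = e_u * ((c0c + g * (u - t0c)) / theta - g / theta**2)
    lower = e_0 * (c0c / theta - g / theta**2)
    out = np.sum(np.where(active, upper - lower, 0.0), axis=0)
    return out


def _frame_values(model_curve, schedule: FrameSchedule, frame_eval: str) -> np.ndarray:
    """Evaluate a continuous model curve per frame.

    ``frame_eval='midpoint'`` evaluates at frame mid-times; ``'average'``
    integrates over each frame with 5-point Gauss-Legendre quadrature.
    """
    if frame_eval == "midpoint":
        return model_curve(schedule.mid_times)
    if frame_eval == "average":
        nodes, wts = np.polynomial.legendre.leggauss(5)
        a, b = schedule.start_times, schedule.end_times
        vals = np.zeros(schedule.n_frames)
        for x, w in zip(nodes, wts):
            t = 0.5 * (b - a) * x + 0.5 * (a + b)
            vals += w * model_curve(t)
        return vals / 2.0  # weights sum to 2; mean over frame
    raise ValueError(f"unknown frame_eval {frame_eval!r}")


def _check_schedule_support(schedule: FrameSchedule, times: np.ndarray, frame_eval: str):
    needed = schedule.mid_times[-1] if frame_eval == "midpoint" else schedule.end_times[-1]
    if needed > times[-1] + 1e-9:
        raise ValueError(
            f"frame schedule needs the input out to {needed:.2f} min, "
            f"beyond its support ({times[-1]:.2f} min)"
        )


def simulate_tac_2tc(
    params: PK2TC,
    aif: ArterialInputFunction,
    schedule: FrameSchedule,
    frame_eval: str = "midpoint",
    **labels,
) -> TimeActivityCurve:
    """Noiseless 2TC tissue curve: C_T = IRF (x) C_p with a bi-exponential
    impulse response whose rates are the roots of
    theta^2 - (k2 + k3 + k4) theta + k2 k4 = 0."""
    _check_schedule_support(schedule, aif.times, frame_eval)
    k2, k3, k4 = params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    theta1 = 0.5 * (s + disc)
    theta2 = 0.5 * (s - disc)
    if theta1 - theta2 < 1e-12:  # degenerate equal roots; nudge apart
        theta1 += 1e-9
    phi1 = params.K1 * (theta1 - k3 - k4) / (theta1 - theta2)
    phi2 = params.K1 * (k3 + k4 - theta2) / (theta1 - theta2)

    def curve(t):
        return phi1 * exp_conv(theta1, aif.times, aif.concentrations, t) + phi2 * exp_conv(
            theta2, aif.times, aif.concentrations, t
        )

    return TimeActivityCurve(schedule, _frame_values(curve, schedule, frame_eval), **labels)


def simulate_tac_1tc(
    params: PK1TC,
    aif: ArterialInputFunction,
    schedule: FrameSchedule,
    frame_eval: str = "midpoint",
    **labels,
) -> TimeActivityCurve:
    """Noiseless 1TC tissue curve: C_T = K1 exp(-k2 t) (x) C_p."""
    _check_schedule_support(schedule, aif.times, frame_eval)

    def curve(t):
        return params.K1 * exp_conv(params.k2, aif.times, aif.concentrations, t)

    return TimeActivityCurve(schedule, _frame_values(curve, schedule, frame_eval), **labels)


def simulate_tac_srtm(
    params: PKSRTM,
    reference_tac: TimeActivityCurve,
    schedule: FrameSchedule,
    frame_eval: str = "midpoint",
    **labels,
) -> TimeActivityCurve:
    """Noiseless SRTM target curve from a reference-region curve:

    C_T = R1 C_R + (k2 - R1 k2a) * (C_R (x) exp(-k2a t)).

    The reference curve is interpolated linearly on its frame mid-times and
    should be sampled finely enough for that interpolation to be accurate.
    """
    ref_t = np.concatenate([[0.0], reference_tac.frame_schedule.mid_times])
    ref_c = np.concatenate([[0.0], reference_tac.values])
    _check_schedule_support(schedule, ref_t, frame_eval)
    k2, k2a = params.k2, params.k2a

    def curve(t):
        return params.R1 * np.interp(t, ref_t, ref_c) + (k2 - params.R1 * k2a) * exp_conv(
            k2a, ref_t, ref_c, t
        )

    return TimeActivityCurve(schedule, _frame_values(curve, schedule, frame_eval), **labels)


def compute_weights(
    tac: TimeActivityCurve,
    isotope_halflife: float = CARBON11_HALFLIFE_MIN,
    floor_fraction: float = 0.05,
) -> np.ndarray:
    """Relative NLS weights from an approximate counts model.

    The variance of frame f is taken proportional to
    ``C_f * exp(lambda t_f) / Delta_f`` (decay-corrected activity divided by
    frame duration, lambda = ln2 / half-life), so weights are its reciprocal.
    Frame activities are floored at ``floor_fraction * max(C)`` to keep
    near-zero early frames from dominating.  Weights are normalised to mean
    one and are invariant to rescaling the curve.
    """
    if isotope_halflife <= 0:
        raise ValueError("isotope half-life must be positive")
    values = np.abs(tac.values)
    peak = values.max()
    if peak <= 0:
        raise ValueError("cannot compute weights for an all-zero curve")
    lam = np.log(2.0) / isotope_halflife
    c = np.maximum(values, floor_fraction * peak)
    var = c * np.exp(lam * tac.frame_schedule.mid_times) / tac.frame_schedule.durations
    w = 1.0 / var
    return w / w.mean()


def make_default_schedule() -> FrameSchedule:
    """Generic 20-frame, 90-minute carbon-11 schedule used by the synthetic
    study presets."""
    durations = [0.5] * 4 + [1.0] * 4 + [2.0] * 2 + [5.0] * 4 + [10.0] * 6
    return FrameSchedule.from_durations(durations)


def make_synthetic_aif(t_end: float = 90.0) -> ArterialInputFunction:
    """Synthetic arterial input: a gamma-variate bolus plus a slow washout
    tail, through (0, 0), sampled densely over the first minutes."""
    t = np.concatenate([np.arange(0.0, 5.0, 0.01), np.arange(5.0, t_end + 0.25, 0.25)])
    c = 60.0 * t * np.exp(-3.0 * t) + 0.8 * np.exp(-0.03 * t) * (1.0 - np.exp(-3.0 * t))
    c[0] = 0.0
    return ArterialInputFunction(t, c)
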