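"""Three-gamma canonical HRF with an initial dip, and designed regressors.

The canonical hemodynamic response function (cHRF) is modelled as a signed
sum of three gamma probability densities::

    cHRF(t) = -A_dip * g(t; a_dip, b_dip)
              + A_main * g(t; a_main, b_main)
              - A_under * g(t; a_under, b_under)

where ``g(t; a, b)`` is the gamma density with shape ``a`` and scale ``b``.
The first (negative) component is the initial dip — the brief decrease in
oxygenated haemoglobin caused by oxygen extraction at task onset, reaching
its extremum near 2 s and resolving by about 4 s.  The second is the
delayed positive blood-flow response peaking near 6 s, and the third the
post-stimulus undershoot.

The designed HRF (dHRF) used as the GLM regressor is the cHRF convolved
with the task boxcar, scaled by the sample interval so it approximates the
continuous-time convolution integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import gamma as gamma_dist

__all__ = [
    "GammaComponent",
    "GammaHrfParams",
    "DesignRegressor",
    "HrfParameterError",
    "chrf",
    "dhrf",
    "restrict_window",
    "single_trial_boxcar",
]


class HrfParameterError(ValueError):
    """Raised for non-physical gamma-kernel parameters."""


@dataclass(frozen=True)
class GammaComponent:
    """One signed gamma-density component of the cHRF.

    ``amplitude`` scales a unit-area gamma density with shape ``shape`` and
    scale ``scale`` (seconds); ``sign`` is -1 for the dip and undershoot,
    +1 for the main response.  The density peaks at ``(shape - 1) * scale``.
    """

    amplitude: float
    shape: float
    scale: float
    sign: int

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise HrfParameterError("amplitude must be >= 0")
        if self.shape <= 0 or self.scale <= 0:
            raise HrfParameterError("gamma shape and scale must be positive")
        if self.sign not in (-1, 1):
            raise HrfParameterError("sign must be -1 or +1")

    @property
    def peak_s(self) -> float:
        return max(self.shape - 1.0, 0.0) * self.scale


def _default_dip() -> GammaComponent:
    return GammaComponent(amplitude=0.35, shape=5.0, scale=0.5, sign=-1)


def _default_main() -> GammaComponent:
    return GammaComponent(amplitude=1.0, shape=7.0, scale=1.0, sign=+1)


def _default_undershoot() -> GammaComponent:
    return GammaComponent(amplitude=0.35, shape=17.0, scale=1.0, sign=-1)


@dataclass(frozen=True)
class GammaHrfParams:
    """Parameters of the three-component cHRF.

    Defaults place the dip extremum near 2 s, the main peak near 6 s and
    the undershoot trough near 16 s, with dip and undershoot at 35% of the
    main amplitude.
    """

    dip: GammaComponent = field(default_factory=_default_dip)
    main: GammaComponent = field(default_factory=_default_main)
    undershoot: GammaComponent = field(default_factory=_default_undershoot)

    def __post_init__(self) -> None:
        if self.dip.sign != -1 or self.undershoot.sign != -1:
            raise HrfParameterError("dip and undershoot must have sign -1")
        if self.main.sign != +1:
            raise HrfParameterError("main response must have sign +1")

    def components(self) -> tuple[GammaComponent, GammaComponent, GammaComponent]:
        return (self.dip, self.main, self.undershoot)

    def to_dict(self) -> dict:
        return {
            name: {
                "amplitude": c.amplitude,
                "shape": c.shape,
                "scale": c.scale,
                "sign": c.sign,
            }
            for name, c in zip(("dip", "main", "undershoot"), self.components())
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GammaHrfParams":
        return cls(**{name: GammaComponent(**d[name]) for name in ("dip", "main", "undershoot")})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "GammaHrfParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def chrf(t: np.ndarray, params: GammaHrfParams | None = None) -> np.ndarray:
    """Evaluate the three-gamma cHRF on a time grid (seconds).

    The grid must be non-negative and increasing.  The value at t = 0 is 0
    because every gamma density with shape > 1 vanishes at the origin.
    """
    params = params or GammaHrfParams()
    t = np.asarray(t, dtype=np.float64)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("time grid must be non-negative and strictly increasing")
    out = np.zeros_like(t)
    for c in params.components():
        out += c.sign * c.amplitude * gamma_dist.pdf(t, c.shape, scale=c.scale)
    return out


@dataclass(frozen=True)
class DesignRegressor:
    """dHRF samples on a trial grid, with the window they cover."""

    samples: np.ndarray
    fs: float
    window_s: float

    def __len__(self) -> int:
        return len(self.samples)


def single_trial_boxcar(task_s: float = 10.0, rest_s: float = 20.0, fs: float = 9.19) -> np.ndarray:
    """0/1 task indicator for one trial (task then rest) at rate ``fs``."""
    n = math.floor((task_s + rest_s) * fs)
    t = np.arange(n) / fs
    return (t < task_s - 1e-12).astype(np.float64)


def dhrf(chrf_samples: np.ndarray, boxcar: np.ndarray, fs: float) -> DesignRegressor:
    """Designed HRF: causal convolution of cHRF with the task boxcar.

    Discrete linear convolution scaled by ``1/fs`` (left Riemann sum of the
    continuous convolution), truncated to the boxcar's length so the
    regressor aligns sample-for-sample with trial data.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    chrf_samples = np.asarray(chrf_samples, dtype=np.float64)
    boxcar = np.asarray(boxcar, dtype=np.float64)
    full = np.convolve(boxcar, chrf_samples)[: len(boxcar)] / fs
    return DesignRegressor(samples=full, fs=fs, window_s=len(boxcar) / fs)


def restrict_window(reg: DesignRegressor, window_s: float, fs: float | None = None) -> DesignRegressor:
    """Keep the first ``floor(window_s * fs)`` samples of a regressor.

    The analysis windows are the initial-dip durations 0.5–4 s (0.5 s
    steps) and 14 s for the delayed response.
    """
    fs = reg.fs if fs is None else fs
    if fs != reg.fs:
        raise ValueError(f"sampling-rate mismatch: {fs} != {reg.fs}")
    if window_s <= 0:
        raise ValueError("window must be positive")
    n = math.floor(window_s * fs)
    if n > len(reg.samples):
        raise ValueError(
            f"window {window_s} s needs {n} samples but the regressor has {len(reg.samples)}"
        )
    return DesignRegressor(samples=reg.samples[:n].copy(), fs=fs, window_s=window_s)
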