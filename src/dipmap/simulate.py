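"""Synthetic finger-tapping fNIRS sessions with known ground truth.

No public recordings exist for the two-task finger-tapping paradigm this
package analyses, so every downstream stage is exercised on simulated
multi-channel ΔHbO.  The simulator emulates the features that matter to
the analysis:

* a 36-channel optode patch over the left motor cortex (6 x 6 grid by
  default; real coordinates are injectable from JSON);
* two task classes (right-hand thumb vs little finger tapping, RHTF and
  RHLF) whose *focal* activation footprints are small, distinct channel
  subsets of the same patch;
* hemodynamics built from the three-gamma cHRF, so active channels show
  an initial dip (ΔHbO decrease over 0–4 s, extremum near 2 s), the
  delayed positive response and an undershoot;
* a spatially *unspecific* delayed vascular component shared by both
  tasks: the blood-flow response washes over the whole patch (weighted by
  a Gaussian of the distance to the patch centre), reflecting the
  physiological premise that the dip localises neuronal activity better
  than the delayed response does;
* physiological nuisance: cardiac, respiratory and Mayer-wave
  oscillations with random per-channel phase, linear drift, and white
  measurement noise.

All randomness flows through a single seed; identical seeds reproduce a
cohort bit-exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hrf import GammaHrfParams, GammaComponent, chrf
from .protocol import SessionProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelGeometry",
    "ActivationProfile",
    "NoiseParams",
    "HbTimeSeries",
    "default_geometry",
    "default_profiles",
    "simulate_session",
    "make_cohort",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Planar layout of measurement channels, coordinates in [0, 1]^2."""

    channel_ids: tuple[str, ...]
    xy: np.ndarray
    emitters: tuple[str, ...] = ()
    detectors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=np.float64)
        object.__setattr__(self, "xy", xy)
        if xy.shape != (len(self.channel_ids), 2):
            raise ValueError("xy must be (n_channels, 2)")
        if len({tuple(p) for p in xy.tolist()}) != len(self.channel_ids):
            raise ValueError("channel coordinates must be pairwise distinct")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.channel_ids)}
        try:
            return np.array([lookup[c] for c in ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"unknown channel id {err.args[0]!r}") from None

    def to_json(self, path) -> None:
        payload = [
            {"channel": c, "x": float(x), "y": float(y)}
            for c, (x, y) in zip(self.channel_ids, self.xy)
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ChannelGeometry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            channel_ids=tuple(rec["channel"] for rec in payload),
            xy=np.array([[rec["x"], rec["y"]] for rec in payload]),
        )


def default_geometry() -> ChannelGeometry:
    """36 channels on a regular 6 x 6 grid spanning [0.1, 0.9]^2.

    The real emitter/detector coordinates of the C3-centred patch are not
    published; the grid stands in for them and can be replaced from JSON.
    """
    lin = np.linspace(0.1, 0.9, 6)
    gx, gy = np.meshgrid(lin, lin)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    ids = tuple(f"CH{i + 1:02d}" for i in range(36))
    emitters = tuple(f"E{i + 1}" for i in range(12))
    detectors = tuple(f"D{i + 1}" for i in range(3))
    return ChannelGeometry(channel_ids=ids, xy=xy, emitters=emitters, detectors=detectors)


@dataclass(frozen=True)
class ActivationProfile:
    """Ground-truth activation of one task class.

    ``active_channels`` carry, at ``amplitude`` µM, the focal response:
    the initial dip plus ``focal_delayed_fraction`` of the delayed
    (main + undershoot) components.  Every channel additionally receives
    the shared delayed-only vascular component at ``spread_amplitude`` µM,
    weighted by a Gaussian (width ``spread_sigma``, unit-square distance)
    of its distance to the patch centre — the task-unspecific blood-flow
    response that makes delayed-window maps look alike for both tasks.
    ``jitter_sd`` is the sigma of the multiplicative lognormal
    trial-to-trial amplitude jitter shared by all channels;
    ``channel_gain_sd`` the sigma of the per-channel, per-trial vascular
    gain jitter; ``spread_center_jitter_sd`` lets the vascular blob's
    centre wander from trial to trial, which makes the delayed-window
    spatial pattern fluctuate coherently across channels.  ``vaso_sd`` is
    the rms (µM, at the blob centre) of spontaneous vascular fluctuation:
    per-channel band-limited noise (``vaso_band``, default 0.01–0.08 Hz,
    the vasomotion range) weighted by the same blob profile — in real
    recordings this task-unlocked low-frequency physiology, not detector
    noise, dominates the analysis band.  Being slow, it is nearly
    constant within short initial-dip windows (absorbed by the fit's
    intercept) but acts as a trend over delayed-response windows.
    """

    class_label: str
    active_channels: tuple[str, ...]
    amplitude: float = 3.0
    jitter_sd: float = 0.2
    spread_amplitude: float = 6.0
    spread_sigma: float = 0.5
    spread_center: tuple[float, float] = (0.5, 0.5)
    spread_center_jitter_sd: float = 0.08
    focal_delayed_fraction: float = 0.05
    channel_gain_sd: float = 0.25
    vaso_sd: float = 1.75
    vaso_band: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.spread_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.jitter_sd < 0 or self.channel_gain_sd < 0 or self.spread_center_jitter_sd < 0:
            raise ValueError("jitter and gain sigmas must be >= 0")
        if self.vaso_sd < 0:
            raise ValueError("vaso_sd must be >= 0")
        if not 0 <= self.focal_delayed_fraction <= 1:
            raise ValueError("focal_delayed_fraction must lie in [0, 1]")


def default_profiles(
    geometry: ChannelGeometry | None = None,
    amplitude: float = 3.0,
    spread_amplitude: float | None = None,
) -> tuple[ActivationProfile, ActivationProfile]:
    """Disjoint focal footprints for the two tapping tasks.

    On the default 6 x 6 grid the thumb (RHTF) footprint is a 2 x 4 block
    on the left edge of rows 2–5 and the little-finger (RHLF) footprint
    the mirrored block on the right edge — distinct sub-areas of one
    patch, consistent with the somatotopy of adjacent digits.  The shared
    delayed vascular component defaults to twice the focal amplitude.
    """
    geometry = geometry or default_geometry()
    ids = geometry.channel_ids
    spread = 2.0 * amplitude if spread_amplitude is None else spread_amplitude
    # rows are blocks of 6 consecutive ids on the default grid
    rhtf = tuple(ids[r * 6 + c] for r in (1, 2, 3, 4) for c in (0, 1))
    rhlf = tuple(ids[r * 6 + c] for r in (1, 2, 3, 4) for c in (4, 5))
    return (
        ActivationProfile(class_label="RHTF", active_channels=rhtf,
                          amplitude=amplitude, spread_amplitude=spread),
        ActivationProfile(class_label="RHLF", active_channels=rhlf,
                          amplitude=amplitude, spread_amplitude=spread),
    )


@dataclass(frozen=True)
class NoiseParams:
    """Additive nuisance model: oscillations, drift and white noise.

    Frequencies in Hz, amplitudes and sd in µM, drift in µM/s.  Cardiac
    (1.2 Hz) and respiratory (0.3 Hz) components lie outside the
    0.01–0.15 Hz analysis band; the Mayer wave (0.1 Hz) lies inside it.
    """

    cardiac_freq: float = 1.2
    cardiac_amp: float = 0.08
    respiratory_freq: float = 0.3
    respiratory_amp: float = 0.06
    mayer_freq: float = 0.1
    mayer_amp: float = 0.03
    drift_slope: float = 0.002
    white_sd: float = 0.375

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "respiratory_amp", "mayer_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cardiac_freq", "respiratory_freq", "mayer_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def silent(cls) -> "NoiseParams":
        return cls(cardiac_amp=0, respiratory_amp=0, mayer_amp=0, drift_slope=0, white_sd=0)


@dataclass
class HbTimeSeries:
    """Channels x samples ΔHbO matrix with its acquisition context."""

    data: np.ndarray
    fs: float
    protocol: SessionProtocol
    geometry: ChannelGeometry
    truth: ActivationProfile | None = None
    label: str | None = None
    subject: int | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.geometry.n_channels, self.protocol.n_samples)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "HbTimeSeries":
        return HbTimeSeries(
            data=data,
            fs=self.fs,
            protocol=self.protocol,
            geometry=self.geometry,
            truth=self.truth,
            label=self.label,
            subject=self.subject,
            session=self.session,
        )


def _per_trial_responses(
    protocol: SessionProtocol, kernel: np.ndarray, fs: float
) -> np.ndarray:
    """(n_trials, n_samples) responses from convolving per-trial boxcars."""
    n = protocol.n_samples
    out = np.zeros((protocol.n_trials, n))
    onsets = protocol.onsets()
    # samples k with k/fs < task_s, matching the single-trial boxcar
    task_n = math.ceil(protocol.task_s * fs - 1e-9)
    for i, onset in enumerate(onsets):
        box = np.zeros(n)
        box[onset : onset + task_n] = 1.0
        out[i] = np.convolve(box, kernel)[:n] / fs
    return out


def _delayed_only(params: GammaHrfParams) -> GammaHrfParams:
    """cHRF with the dip removed: the spatially unspecific vascular part."""
    zero_dip = GammaComponent(amplitude=0.0, shape=params.dip.shape, scale=params.dip.scale, sign=-1)
    return replace(params, dip=zero_dip)


def _focal(params: GammaHrfParams, delayed_fraction: float) -> GammaHrfParams:
    """cHRF of the focal response: full dip, attenuated delayed components."""
    return replace(
        params,
        main=replace(params.main, amplitude=params.main.amplitude * delayed_fraction),
        undershoot=replace(params.undershoot, amplitude=params.undershoot.amplitude * delayed_fraction),
    )


def simulate_session(
    protocol: SessionProtocol,
    geometry: ChannelGeometry,
    profile: ActivationProfile,
    noise: NoiseParams,
    hrf_params: GammaHrfParams | None = None,
    seed: int | np.random.Generator = 0,
    subject_gain: float = 1.0,
) -> HbTimeSeries:
    """Simulate one session of multi-channel ΔHbO for one task class.

    Active channels carry ``subject_gain * amplitude`` times the focal
    dHRF (dip plus the attenuated delayed components) time-locked to each
    trial onset; all channels carry the shared delayed vascular component
    weighted by distance to the patch centre.  Both are modulated by the
    session-wide per-trial jitter and the per-channel, per-trial vascular
    gain; nuisance noise is added on top.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hrf_params = hrf_params or GammaHrfParams()
    fs = protocol.fs
    n_ch, n = geometry.n_channels, protocol.n_samples
    active_idx = geometry.index_of(profile.active_channels)

    t_kernel = np.arange(math.floor(40.0 * fs)) / fs  # HRF support, covers undershoot tail
    focal_kernel = chrf(t_kernel, _focal(hrf_params, profile.focal_delayed_fraction))
    delayed_kernel = chrf(t_kernel, _delayed_only(hrf_params))

    data = np.zeros((n_ch, n))
    if protocol.n_trials:
        resp_focal = _per_trial_responses(protocol, focal_kernel, fs)
        resp_delayed = _per_trial_responses(protocol, delayed_kernel, fs)
        if profile.jitter_sd > 0:
            jitter = rng.lognormal(mean=0.0, sigma=profile.jitter_sd, size=protocol.n_trials)
        else:
            jitter = np.ones(protocol.n_trials)
        if profile.channel_gain_sd > 0:
            gain = rng.lognormal(0.0, profile.channel_gain_sd, size=(n_ch, protocol.n_trials))
        else:
            gain = np.ones((n_ch, protocol.n_trials))
        trial_w = gain * jitter[None, :]  # (n_ch, n_trials)
        centers = np.asarray(profile.spread_center) + (
            rng.normal(0.0, profile.spread_center_jitter_sd, size=(protocol.n_trials, 2))
            if profile.spread_center_jitter_sd > 0
            else np.zeros((protocol.n_trials, 2))
        )
        for i in range(protocol.n_trials):
            d2 = np.sum((geometry.xy - centers[i]) ** 2, axis=1)
            spread_w = np.exp(-d2 / (2 * profile.spread_sigma**2))
            data += (
                subject_gain * profile.spread_amplitude
                * (spread_w * trial_w[:, i])[:, None] * resp_delayed[i][None, :]
            )
        data[active_idx] += (
            subject_gain * profile.amplitude * (trial_w[active_idx] @ resp_focal)
        )

    if profile.vaso_sd > 0 and n >= 32:
        from .preprocessing import FilterSpec, bandpass

        lo, hi = profile.vaso_band
        lf = bandpass(rng.normal(size=(n_ch, n)), FilterSpec(fs=fs, low_cut=lo, high_cut=hi))
        lf /= lf.std(axis=1, keepdims=True) + 1e-30
        d2 = np.sum((geometry.xy - np.asarray(profile.spread_center)) ** 2, axis=1)
        w0 = np.exp(-d2 / (2 * profile.spread_sigma**2))
        data += profile.vaso_sd * w0[:, None] * lf

    t = protocol.time()
    for freq, amp in (
        (noise.cardiac_freq, noise.cardiac_amp),
        (noise.respiratory_freq, noise.respiratory_amp),
        (noise.mayer_freq, noise.mayer_amp),
    ):
        if amp > 0:
            phases = rng.uniform(0, 2 * np.pi, size=n_ch)
            data += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    if noise.drift_slope:
        signs = rng.choice([-1.0, 1.0], size=n_ch)
        data += noise.drift_slope * np.outer(signs, t)
    if noise.white_sd > 0:
        data += rng.normal(0.0, noise.white_sd, size=(n_ch, n))

    return HbTimeSeries(
        data=data, fs=fs, protocol=protocol, geometry=geometry,
        truth=profile, label=profile.class_label,
    )


def make_cohort(
    n_subjects: int,
    n_trials: int,
    profile_rhtf: ActivationProfile,
    profile_rhlf: ActivationProfile,
    noise: NoiseParams,
    seed: int = 0,
    protocol: SessionProtocol | None = None,
    geometry: ChannelGeometry | None = None,
    hrf_params: GammaHrfParams | None = None,
    subject_gain_sd: float = 0.15,
) -> list[HbTimeSeries]:
    """Simulate ``2 * n_subjects`` labelled sessions (one per task class).

    Each subject's overall response gain is drawn once (lognormal, sigma
    ``subject_gain_sd``) and shared by both of their sessions; within a
    session, trial amplitudes jitter around that gain.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if set(profile_rhtf.active_channels) == set(profile_rhlf.active_channels):
        logger.warning("the two task profiles have identical focal footprints")
    protocol = protocol or SessionProtocol()
    if n_trials != protocol.n_trials:
        protocol = replace(protocol, n_trials=n_trials)
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    sessions: list[HbTimeSeries] = []
    for subj in range(n_subjects):
        gain = float(rng.lognormal(0.0, subject_gain_sd)) if subject_gain_sd > 0 else 1.0
        for sess_idx, profile in enumerate((profile_rhtf, profile_rhlf)):
            ts = simulate_session(
                protocol, geometry, profile, noise,
                hrf_params=hrf_params, seed=rng, subject_gain=gain,
            )
            ts.subject = subj
            ts.session = sess_idx
            sessions.append(ts)
    return sessions
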