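"""Finger-tapping session protocol and task boxcar construction.

A session is ``pre_rest | n_trials x (task + rest) | post_rest``, sampled at
a fixed rate.  The default protocol is 60 s pre-rest, six trials of 10 s
tapping followed by 20 s rest, and 10 s post-rest, recorded at 9.19 Hz.
Sample counts are truncated with ``floor(duration * fs)`` so that a 30 s
trial at 9.19 Hz spans 275 samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SessionProtocol", "ProtocolError", "build_boxcar"]


class ProtocolError(ValueError):
    """Raised for physically invalid protocol specifications."""


@dataclass(frozen=True)
class SessionProtocol:
    """Timing structure of one finger-tapping session.

    Parameters
    ----------
    pre_rest_s, post_rest_s : float
        Leading and trailing rest durations in seconds.
    n_trials : int
        Number of task trials.
    task_s, rest_s : float
        Tapping and within-trial rest durations in seconds.
    fs : float
        Sampling rate in Hz.
    """

    pre_rest_s: float = 60.0
    post_rest_s: float = 10.0
    n_trials: int = 6
    task_s: float = 10.0
    rest_s: float = 20.0
    fs: float = 9.19

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ProtocolError(f"sampling rate must be positive, got {self.fs}")
        for name in ("pre_rest_s", "post_rest_s", "task_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        if self.n_trials < 0:
            raise ProtocolError("n_trials must be >= 0")

    @property
    def trial_s(self) -> float:
        """Length of one trial (task + rest) in seconds."""
        return self.task_s + self.rest_s

    @property
    def total_s(self) -> float:
        """Total session duration in seconds."""
        return self.pre_rest_s + self.n_trials * self.trial_s + self.post_rest_s

    @property
    def n_samples(self) -> int:
        """Number of samples in the session, ``floor(total_s * fs)``."""
        return math.floor(self.total_s * self.fs)

    @property
    def samples_per_trial(self) -> int:
        """Samples in one trial, ``floor(trial_s * fs)`` (275 under defaults)."""
        return math.floor(self.trial_s * self.fs)

    def time(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return np.arange(self.n_samples) / self.fs

    def onsets(self) -> np.ndarray:
        """Sample index of the first task sample of each trial."""
        t = self.time()
        starts = self.pre_rest_s + np.arange(self.n_trials) * self.trial_s
        # first sample with t >= start
        return np.searchsorted(t, starts - 1e-12, side="left").astype(np.int64)

    def boxcar(self) -> np.ndarray:
        """Per-sample 0/1 task indicator over the whole session."""
        t = self.time()
        rel = t - self.pre_rest_s
        in_block = (rel >= -1e-12) & (rel < self.n_trials * self.trial_s - 1e-12)
        phase = np.mod(rel, self.trial_s)
        box = (in_block & (phase < self.task_s - 1e-12)).astype(np.float64)
        return box


def build_boxcar(spec: SessionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Task boxcar and trial onset indices for a protocol.

    Returns
    -------
    boxcar : ndarray of shape (n_samples,)
        1.0 during tapping, 0.0 otherwise.
    onsets : ndarray of shape (n_trials,)
        Sample index at which each trial's task segment begins.
    """
    return spec.boxcar(), spec.onsets()
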