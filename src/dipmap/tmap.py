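"""Per-trial robust-regression activation t-maps.

For every trial and channel, the windowed ΔHbO samples are regressed on
the equally windowed designed HRF with iteratively reweighted least
squares (bisquare weights, tuning constant 4.685, residual scale
MAD/0.6745) — the robust linear fit popularised by MATLAB's ``robustfit``.
The slope t-value measures how strongly the channel follows the expected
hemodynamics within the window.  Channels with t > t_crt (1.65) and
one-sided p < 0.05 keep their t-value, all others are set to 0; surviving
values are normalised to [0, 1] and interpolated over the optode patch to
render a fixed-size functional activation image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import griddata

from .hrf import DesignRegressor, GammaHrfParams, chrf, dhrf, restrict_window, single_trial_boxcar
from .simulate import ChannelGeometry, HbTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RobustFitResult",
    "TMapParams",
    "TMap",
    "ImageDataset",
    "SingularDesignError",
    "InsufficientDataError",
    "robust_fit",
    "t_to_activation",
    "render_tmap",
    "trial_regressor",
    "build_dataset",
    "jet_colormap",
]

BISQUARE_TUNE = 4.685
MAD_TO_SD = 0.6745
MAX_ITER = 50
COEF_TOL = 1e-6


class SingularDesignError(ValueError):
    """Regressor carries no variation: the slope is not identifiable."""


class InsufficientDataError(ValueError):
    """Too few samples for a two-parameter robust fit."""


@dataclass(frozen=True)
class RobustFitResult:
    """Output of one per-channel robust regression."""

    beta0: float
    beta1: float
    se1: float
    t: float
    p: float
    df: int
    weights: np.ndarray
    n_iter: int


def _bisquare(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return w


def _bisquare_psi(u: np.ndarray) -> np.ndarray:
    inside = np.abs(u) < 1
    return np.where(inside, u * (1 - u**2) ** 2, 0.0)


def _bisquare_dpsi(u: np.ndarray) -> np.ndarray:
    inside = np.abs(u) < 1
    return np.where(inside, (1 - u**2) * (1 - 5 * u**2), 0.0)


def robust_fit(
    y: np.ndarray,
    x: np.ndarray,
    df: int | None = None,
    force_unit_weights: bool = False,
) -> RobustFitResult:
    """IRLS regression of ``y`` on ``[1, x]`` with bisquare weights.

    Residuals are leverage-adjusted (divided by sqrt(1 - h)), the robust
    scale is recomputed each iteration as median(|r_adj|)/0.6745, and the
    iteration stops when the largest coefficient change drops below 1e-6
    or after 50 iterations.  The slope standard error uses the
    Street–Carroll–Ruppert robust variance estimate (the one behind
    MATLAB's ``robustfit`` statistics), which keeps the null t-statistic
    close to its nominal Student distribution; the p-value is the
    one-sided upper tail with ``df`` (default n - 2) degrees of freedom.

    Data that fit exactly (zero residual) fall back to the ordinary
    least-squares solution with unit weights, since the robust scale
    degenerates to zero there.  ``force_unit_weights=True`` skips the
    reweighting entirely and returns the textbook OLS estimate, standard
    error and t-value.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be one-dimensional and equally long")
    n = len(y)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 samples, got {n}")
    if np.ptp(x) == 0:
        raise SingularDesignError("constant regressor")
    dof = n - 2 if df is None else df

    X = np.column_stack([np.ones(n), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    q, _ = np.linalg.qr(X)
    h = np.minimum(np.sum(q**2, axis=1), 0.9999)
    adj = 1.0 / np.sqrt(1.0 - h)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale_ref = np.median(np.abs(y - np.median(y))) + np.std(y) + 1e-300
    weights = np.ones(n)
    n_iter = 0
    exact = False
    if force_unit_weights:
        r = y - X @ beta
        sigma2 = float(r @ r) / (n - 2)
        se1 = math.sqrt(sigma2 * xtx_inv[1, 1])
        t_val = beta[1] / se1 if se1 > 0 else 0.0
        return RobustFitResult(
            beta0=float(beta[0]), beta1=float(beta[1]), se1=se1,
            t=float(t_val), p=float(stats.t.sf(t_val, dof)) if se1 > 0 else 1.0,
            df=dof, weights=weights, n_iter=0,
        )
    for n_iter in range(1, MAX_ITER + 1):
        r = y - X @ beta
        radj = r * adj
        s = np.median(np.abs(radj)) / MAD_TO_SD
        if s <= 1e-12 * scale_ref:
            weights = np.ones(n)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            exact = True
            break
        u = radj / (BISQUARE_TUNE * s)
        weights = _bisquare(u)
        if not np.any(weights > 0):  # pathological: every point flagged
            weights = np.ones(n)
        xtw = X.T * weights
        beta_new = np.linalg.solve(xtw @ X, xtw @ y)
        if np.max(np.abs(beta_new - beta)) < COEF_TOL:
            beta = beta_new
            break
        beta = beta_new

    r = y - X @ beta
    if exact:
        se1 = 0.0
    else:
        s0 = np.median(np.abs(r * adj)) / MAD_TO_SD
        u = (r * adj) / (BISQUARE_TUNE * s0)
        psi = _bisquare_psi(u)
        dpsi = _bisquare_dpsi(u)
        m1 = dpsi.mean()
        if m1 > 1e-8:
            # Street, Carroll & Ruppert (1988) variance with the small-sample
            # correction factor K used by robustfit
            k_corr = 1.0 + 2.0 * np.var(dpsi) / (n * m1**2)
            s2 = (
                k_corr**2 * (n / (n - 2))
                * (BISQUARE_TUNE * s0) ** 2 * np.mean(psi**2) / m1**2
            )
        else:  # nearly everything downweighted: fall back to the MAD scale
            s2 = s0**2
        se1 = math.sqrt(max(s2 * xtx_inv[1, 1], 0.0))
    if se1 > 0:
        t_val = beta[1] / se1
        p_val = float(stats.t.sf(t_val, dof))
    else:
        t_val = math.inf if beta[1] > 0 else (-math.inf if beta[1] < 0 else 0.0)
        p_val = 0.0 if beta[1] > 0 else 1.0
    return RobustFitResult(
        beta0=float(beta[0]), beta1=float(beta[1]), se1=float(se1),
        t=float(t_val), p=p_val, df=dof, weights=weights, n_iter=n_iter,
    )


@dataclass(frozen=True)
class TMapParams:
    """Thresholding and rendering parameters for activation maps."""

    t_crt: float = 1.65
    alpha: float = 0.05
    window_s: float = 4.0
    image_size: int = 227
    grayscale: bool = False

    def __post_init__(self) -> None:
        if self.t_crt <= 0:
            raise ValueError("t_crt must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")


def t_to_activation(t: np.ndarray, p: np.ndarray, params: TMapParams) -> np.ndarray:
    """Threshold t-values at (t > t_crt, p < alpha) and scale to [0, 1].

    Surviving channels keep their t-value; the vector is then divided by
    its maximum, so the strongest surviving channel maps to exactly 1.
    An all-suppressed map stays identically zero.  Channels whose data fit
    the regressor exactly carry an infinite t-value and saturate at 1,
    with the finite survivors scaled relative to the largest finite one.
    """
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError("t and p must have the same length")
    v = np.where((t > params.t_crt) & (p < params.alpha), t, 0.0)
    if v.size == 0:
        return v
    inf_mask = np.isinf(v)
    if inf_mask.any():
        finite_max = v[~inf_mask].max() if (~inf_mask).any() else 0.0
        if finite_max > 0:
            v = np.where(inf_mask, 1.0, v / finite_max)
        else:
            v = inf_mask.astype(np.float64)
        return v
    m = v.max()
    if m > 0:
        v = v / m
    return v


def jet_colormap(n: int = 256, grayscale: bool = False) -> np.ndarray:
    """Fixed (n, 3) lookup table in [0, 1]; classic blue-to-red ramp."""
    x = np.linspace(0.0, 1.0, n)
    if grayscale:
        return np.repeat(x[:, None], 3, axis=1)
    r = np.clip(1.5 - np.abs(4 * x - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * x - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * x - 1), 0, 1)
    return np.column_stack([r, g, b])


@dataclass
class TMap:
    """One rendered activation map and its provenance."""

    channel_values: np.ndarray
    t_raw: np.ndarray
    p_raw: np.ndarray
    image: np.ndarray
    label: str | None = None
    subject: int | None = None
    trial: int | None = None
    window_s: float | None = None


def render_tmap(
    channel_values: np.ndarray,
    geometry: ChannelGeometry,
    params: TMapParams,
) -> np.ndarray:
    """Interpolate per-channel activation onto an RGB image.

    Channel values are scattered at the optode coordinates, linearly
    interpolated onto an ``image_size``-square grid (nearest-neighbour
    outside the convex hull and whenever fewer than three non-collinear
    channels exist), clipped to [0, 1] and passed through a fixed
    256-entry colormap.  Row 0 of the image is the top of the patch
    (y = 1).
    """
    v = np.asarray(channel_values, dtype=np.float64)
    if v.shape != (geometry.n_channels,):
        raise ValueError("need exactly one value per channel")
    size = params.image_size
    lin = np.linspace(0.0, 1.0, size)
    gx, gy = np.meshgrid(lin, lin[::-1])  # row 0 at y = 1
    pts = geometry.xy
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0)) if len(pts) >= 3 else 0
    if len(pts) < 3 or rank < 2:
        logger.warning("degenerate geometry: falling back to nearest-neighbour rendering")
        grid = griddata(pts, v, (gx, gy), method="nearest")
    else:
        grid = griddata(pts, v, (gx, gy), method="linear")
        mask = np.isnan(grid)
        if mask.any():
            grid[mask] = griddata(pts, v, (gx[mask], gy[mask]), method="nearest")
    grid = np.clip(grid, 0.0, 1.0)
    table = jet_colormap(256, grayscale=params.grayscale)
    idx = np.rint(grid * 255).astype(np.intp)
    return table[idx]


def trial_regressor(
    window_s: float,
    fs: float = 9.19,
    task_s: float = 10.0,
    rest_s: float = 20.0,
    hrf_params: GammaHrfParams | None = None,
) -> DesignRegressor:
    """Windowed single-trial dHRF: one 10 s-on/20 s-off boxcar convolved
    with the cHRF, truncated to the first ``floor(window_s * fs)`` samples."""
    box = single_trial_boxcar(task_s=task_s, rest_s=rest_s, fs=fs)
    kernel_t = np.arange(len(box)) / fs
    reg = dhrf(chrf(kernel_t, hrf_params), box, fs)
    return restrict_window(reg, window_s)


@dataclass
class ImageDataset:
    """Stacked activation images with labels and per-image metadata."""

    images: np.ndarray  # (N, size, size, 3) float32 in [0, 1]
    labels: np.ndarray  # (N,) strings
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels) or len(self.labels) != len(self.meta):
            raise ValueError("images, labels and metadata must align")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        return ImageDataset(
            images=self.images[idx],
            labels=self.labels[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    @staticmethod
    def concat(parts: list["ImageDataset"]) -> "ImageDataset":
        return ImageDataset(
            images=np.concatenate([p.images for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            meta=pd.concat([p.meta for p in parts], ignore_index=True),
        )


def session_tmaps(
    series: HbTimeSeries,
    windows: list[float],
    params: TMapParams,
    hrf_params: GammaHrfParams | None = None,
    fit_mode: str = "window",
) -> list[TMap]:
    """All per-trial, per-window activation maps of one session.

    ``fit_mode='window'`` regresses only the samples
    ``[onset, onset + floor(window_s * fs))`` of each trial on the equally
    windowed regressor; ``fit_mode='full_trial'`` fits the whole 30 s
    trial (274-ish degrees of freedom) and merely tags the map with the
    window.
    """
    if fit_mode not in ("window", "full_trial"):
        raise ValueError("fit_mode must be 'window' or 'full_trial'")
    fs = series.fs
    onsets = series.protocol.onsets()
    regs = {
        w: trial_regressor(
            w if fit_mode == "window" else series.protocol.trial_s,
            fs=fs, task_s=series.protocol.task_s,
            rest_s=series.protocol.rest_s, hrf_params=hrf_params,
        )
        for w in windows
    }
    maps: list[TMap] = []
    for trial_idx, onset in enumerate(onsets):
        for w in windows:
            reg = regs[w]
            n_win = len(reg)
            seg = series.data[:, onset : onset + n_win]
            if seg.shape[1] < n_win:
                raise ValueError(f"window {w} s overruns the session at trial {trial_idx}")
            t_vals = np.empty(series.n_channels)
            p_vals = np.empty(series.n_channels)
            for c in range(series.n_channels):
                res = robust_fit(seg[c], reg.samples)
                t_vals[c], p_vals[c] = res.t, res.p
            act = t_to_activation(t_vals, p_vals, params)
            img = render_tmap(act, series.geometry, params).astype(np.float32)
            maps.append(TMap(
                channel_values=act, t_raw=t_vals, p_raw=p_vals, image=img,
                label=series.label, subject=series.subject,
                trial=trial_idx, window_s=w,
            ))
    return maps


def build_dataset(
    cohort: list[HbTimeSeries],
    windows: list[float],
    params: TMapParams | None = None,
    hrf_params: GammaHrfParams | None = None,
    fit_mode: str = "window",
) -> ImageDataset:
    """Render one activation image per (session, trial, window).

    With 11 subjects, 6 trials per session and 8 initial-dip windows this
    yields 528 images per task class; a single window yields 66.
    """
    params = params or TMapParams()
    images, labels, rows = [], [], []
    for series in cohort:
        for m in session_tmaps(series, windows, params, hrf_params, fit_mode):
            images.append(m.image)
            labels.append(m.label)
            rows.append({
                "subject": m.subject, "session": series.session,
                "trial": m.trial, "window_s": m.window_s, "label": m.label,
            })
    if not images:
        size = (params.image_size, params.image_size, 3)
        return ImageDataset(
            images=np.zeros((0, *size), dtype=np.float32),
            labels=np.array([], dtype="<U8"),
            meta=pd.DataFrame(columns=["subject", "session", "trial", "window_s", "label"]),
        )
    return ImageDataset(
        images=np.stack(images), labels=np.array(labels), meta=pd.DataFrame(rows)
    )
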