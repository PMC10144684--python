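"""Voxel-wise quantitative MRI parameter maps.

Two semi-quantitative maps are computed from standard breast-cancer MRI
protocols:

* the apparent diffusion coefficient (ADC, mm^2/s) from multi-b-value
  diffusion-weighted series, by fitting the monoexponential decay
  ``S(b) = S0 * exp(-ADC * b)`` per voxel;
* the signal enhancement ratio (SER, dimensionless) from dynamic
  contrast-enhanced series,
  ``SER = (S_early - S_baseline) / (S_late - S_baseline)``,
  where ``S_baseline`` averages the pre-contrast frames, ``S_early`` is the
  post-baseline peak, and ``S_late`` is the signal six minutes after the peak.

Both fits run vectorized over all voxels; invalid voxels (outside the mask,
non-positive diffusion signal, non-enhancing dynamic curves) are NaN in the
output map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

#: Upper fitting bound for ADC, mm^2/s. Free water at body temperature is
#: ~3e-3 mm^2/s; 1e-2 leaves generous headroom without admitting runaway fits.
ADC_UPPER_BOUND = 1.0e-2


def _as_spacing(spacing: Sequence[float]) -> np.ndarray:
    sp = np.asarray(spacing, dtype=float)
    if sp.shape != (3,) or not np.all(sp > 0):
        raise InvalidInputError(f"voxel_spacing must be 3 positive values, got {spacing!r}")
    return sp


@dataclass
class DiffusionSeries:
    """4-D diffusion-weighted acquisition, last axis indexed by b-value."""

    voxels: np.ndarray          # (x, y, z, n_b), arbitrary signal units
    b_values: np.ndarray        # s/mm^2, strictly increasing, >= 0
    voxel_spacing: np.ndarray   # mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.voxel_spacing = _as_spacing(self.voxel_spacing)
        if self.voxels.ndim != 4:
            raise InvalidInputError("diffusion voxels must be 4-D (x, y, z, b)")
        if self.b_values.ndim != 1 or len(self.b_values) != self.voxels.shape[3]:
            raise InvalidInputError("b_values length must match the 4th voxel axis")
        if np.any(self.b_values < 0) or np.any(np.diff(self.b_values) <= 0):
            raise InvalidInputError("b_values must be nonnegative and strictly increasing")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class DynamicSeries:
    """4-D dynamic contrast-enhanced acquisition, last axis indexed by frame time."""

    voxels: np.ndarray          # (x, y, z, n_t)
    frame_times: np.ndarray     # seconds, strictly increasing
    voxel_spacing: np.ndarray   # mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.voxel_spacing = _as_spacing(self.voxel_spacing)
        if self.voxels.ndim != 4:
            raise InvalidInputError("dynamic voxels must be 4-D (x, y, z, t)")
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.voxels.shape[3]:
            raise InvalidInputError("frame_times length must match the 4th voxel axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise InvalidInputError("frame_times must be strictly increasing")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class ParameterMap:
    """3-D derived map; NaN marks voxels where the quantity is undefined."""

    values: np.ndarray
    name: str                   # "ADC" or "SER"
    units: str                  # "mm^2/s" or "dimensionless"
    voxel_spacing: np.ndarray
    #: optional per-voxel quality flags (e.g. late frame clamped to end of
    #: acquisition for SER); same shape as ``values``
    quality: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_spacing = _as_spacing(self.voxel_spacing)
        if self.values.ndim != 3:
            raise InvalidInputError("parameter map must be 3-D")
        if self.name not in ("ADC", "SER"):
            raise InvalidInputError(f"unknown map name {self.name!r}")


@dataclass
class ROIMask:
    """Binary 3-D lesion mask sharing the geometry of the series it annotates."""

    mask: np.ndarray
    voxel_spacing: np.ndarray
    label: str = "lesion"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.voxel_spacing = _as_spacing(self.voxel_spacing)
        if self.mask.ndim != 3:
            raise InvalidInputError("ROI mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def predict_diffusion_signal(
    s0: float, adc: float, b_values: Sequence[float]
) -> np.ndarray:
    """Forward monoexponential diffusion model ``S(b) = S0 * exp(-ADC * b)``."""
    if not s0 > 0:
        raise InvalidInputError(f"s0 must be positive, got {s0}")
    if adc < 0:
        raise InvalidInputError(f"adc must be nonnegative, got {adc}")
    b = np.asarray(b_values, dtype=float)
    return s0 * np.exp(-adc * b)


def _loglinear_adc(signal: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS of ln(S) on b. signal: (n_vox, n_b), all > 0.

    Returns (s0, adc) per voxel; this is the fit initializer and is exact on
    noiseless data.
    """
    y = np.log(signal)
    bc = b - b.mean()
    denom = float(np.dot(bc, bc))
    slope = (y @ bc) / denom
    intercept = y.mean(axis=1) - slope * b.mean()
    return np.exp(intercept), -slope


def _refine_exp_fit(
    signal: np.ndarray,
    b: np.ndarray,
    s0: np.ndarray,
    adc: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-14,
) -> tuple[np.ndarray, np.ndarray]:
    """Bounded Levenberg–Marquardt refinement of (S0, ADC), vectorized per voxel.

    Minimizes sum_b (S0 e^(-ADC b) - S(b))^2 with ADC in [0, ADC_UPPER_BOUND]
    and S0 > 0; the 2x2 normal equations are solved in closed form for every
    voxel simultaneously, with per-voxel damping and step acceptance.
    """
    s0 = np.clip(s0.copy(), 1e-300, None)
    adc = np.clip(adc.copy(), 0.0, ADC_UPPER_BOUND)
    lam = np.full(s0.shape, 1e-3)

    def cost(s0v, adcv):
        model = s0v[:, None] * np.exp(-adcv[:, None] * b[None, :])
        r = model - signal
        return (r * r).sum(axis=1), r, model

    c, r, model = cost(s0, adc)
    active = np.ones(s0.shape, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        e = model / s0[:, None]                       # exp(-ADC b) per voxel
        j0 = e                                        # d model / d S0
        j1 = -s0[:, None] * b[None, :] * e            # d model / d ADC
        a00 = (j0 * j0).sum(axis=1)
        a01 = (j0 * j1).sum(axis=1)
        a11 = (j1 * j1).sum(axis=1)
        g0 = (j0 * r).sum(axis=1)
        g1 = (j1 * r).sum(axis=1)
        # damped normal equations (A + lam*diag(A)) d = -g
        d00 = a00 * (1 + lam)
        d11 = a11 * (1 + lam)
        det = d00 * d11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step0 = (-g0 * d11 + g1 * a01) / det
        step1 = (-g1 * d00 + g0 * a01) / det
        new_s0 = np.clip(s0 + step0, 1e-300, None)
        new_adc = np.clip(adc + step1, 0.0, ADC_UPPER_BOUND)
        new_c, new_r, new_model = cost(new_s0, new_adc)
        improved = active & (new_c <= c)
        s0 = np.where(improved, new_s0, s0)
        adc = np.where(improved, new_adc, adc)
        rel = np.abs(new_c - c) / np.maximum(c, 1e-300)
        converged = improved & (rel < tol)
        r = np.where(improved[:, None], new_r, r)
        model = np.where(improved[:, None], new_model, model)
        c = np.where(improved, new_c, c)
        lam = np.where(improved, lam * 0.3, lam * 4.0)
        active = active & ~converged & (lam < 1e12)
    return s0, adc


def fit_adc_map(
    series: DiffusionSeries, mask: Optional[ROIMask] = None
) -> ParameterMap:
    """Fit the ADC map voxel-by-voxel.

    Each voxel's multi-b signal is fit to ``S0 * exp(-ADC * b)`` by bounded
    nonlinear least squares initialized from the closed-form log-linear
    solution. Voxels outside the mask (when given) or with any non-positive
    signal are NaN.
    """
    if len(np.unique(series.b_values)) < 2:
        raise InvalidInputError("ADC fitting requires at least 2 distinct b-values")
    if mask is not None and mask.mask.shape != series.spatial_shape:
        raise InvalidInputError(
            f"mask shape {mask.mask.shape} does not match series {series.spatial_shape}"
        )

    shape = series.spatial_shape
    flat = series.voxels.reshape(-1, series.voxels.shape[3])
    select = np.all(flat > 0, axis=1)
    if mask is not None:
        select &= mask.mask.reshape(-1)

    out = np.full(flat.shape[0], np.nan)
    if select.any():
        sig = flat[select]
        s0, adc = _loglinear_adc(sig, series.b_values)
        adc = np.clip(adc, 0.0, ADC_UPPER_BOUND)
        _, adc = _refine_exp_fit(sig, series.b_values, s0, adc)
        out[select] = adc
    return ParameterMap(
        values=out.reshape(shape),
        name="ADC",
        units="mm^2/s",
        voxel_spacing=series.voxel_spacing,
    )


def compute_ser_map(
    series: DynamicSeries,
    mask: Optional[ROIMask] = None,
    n_baseline: int = 10,
    late_offset: float = 360.0,
    denominator_epsilon: Optional[float] = None,
    peak_mode: str = "voxel",
) -> ParameterMap:
    """Compute the signal enhancement ratio map.

    Per voxel: ``S_baseline`` is the mean of the first ``n_baseline`` frames,
    ``S_early`` the maximum over frames at/after index ``n_baseline`` (earliest
    frame on ties), and ``S_late`` the signal at the frame whose time is
    nearest the peak time plus ``late_offset`` seconds (clamped to the last
    frame, which sets the quality flag). Voxels whose denominator
    ``|S_late - S_baseline|`` falls below ``denominator_epsilon`` (default
    1e-6 times the series maximum) are NaN.

    ``peak_mode="roi"`` instead locates one peak frame on the ROI-mean curve
    (requires a mask) and evaluates every voxel at that shared peak/late frame
    pair, mirroring a whole-ROI reading of the enhancement curve.
    """
    n_frames = series.voxels.shape[3]
    if n_frames < n_baseline + 1:
        raise InvalidInputError(
            f"SER requires at least {n_baseline + 1} frames, got {n_frames}"
        )
    if late_offset <= 0:
        raise InvalidInputError("late_offset must be positive")
    if mask is not None and mask.mask.shape != series.spatial_shape:
        raise InvalidInputError("mask shape does not match series")
    if peak_mode not in ("voxel", "roi"):
        raise InvalidInputError(f"unknown peak_mode {peak_mode!r}")
    if peak_mode == "roi" and mask is None:
        raise InvalidInputError("peak_mode='roi' requires a mask")

    if denominator_epsilon is None:
        denominator_epsilon = 1e-6 * float(np.nanmax(series.voxels))

    times = series.frame_times
    flat = series.voxels.reshape(-1, n_frames)
    s_baseline = flat[:, :n_baseline].mean(axis=1)
    post = flat[:, n_baseline:]

    if peak_mode == "voxel":
        peak_idx = n_baseline + np.argmax(post, axis=1)   # argmax: earliest tie wins
    else:
        roi_curve = flat[mask.mask.reshape(-1)].mean(axis=0)
        peak_idx = np.full(
            flat.shape[0], n_baseline + int(np.argmax(roi_curve[n_baseline:]))
        )
    s_early = np.take_along_axis(flat, peak_idx[:, None], axis=1)[:, 0]
    target_t = times[peak_idx] + late_offset
    late_idx = np.argmin(np.abs(times[None, :] - target_t[:, None]), axis=1)
    clamped = target_t > times[-1]
    s_late = np.take_along_axis(flat, late_idx[:, None], axis=1)[:, 0]

    denom = s_late - s_baseline
    with np.errstate(divide="ignore", invalid="ignore"):
        ser = (s_early - s_baseline) / denom
    ser[np.abs(denom) < denominator_epsilon] = np.nan
    if mask is not None:
        ser[~mask.mask.reshape(-1)] = np.nan

    shape = series.spatial_shape
    return ParameterMap(
        values=ser.reshape(shape),
        name="SER",
        units="dimensionless",
        voxel_spacing=series.voxel_spacing,
        quality=clamped.reshape(shape),
    )
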