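"""Digital co-clinical cohort phantoms with known ground truth.

Generates everything the analysis stages consume, with the generating truth
retained so every derived quantity can be checked analytically:

* diffusion-weighted series whose tumor voxels decay with a known ADC;
* dynamic contrast-enhanced series whose tumor enhancement curve is built to
  invert exactly to a known SER (flat 10-frame baseline, rise to a peak,
  monotone washout through the prescribed 6-minute post-peak level);
* ellipsoidal tumor masks that shrink (responders) or grow/hold steady
  (non-responders) between the T0 and T1 studies;
* baseline expression tables for the patient and PDX cohorts with a planted
  subset of genes whose expression is monotonically coupled to each
  subject's volume change, so association recovery can be tested.

Cohort sizes default to a prototyping-scale co-clinical study: 21 patients
and 9 PDX-bearing mice, each imaged pre- (T0) and on-treatment (T1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .imaging import DiffusionSeries, DynamicSeries, ROIMask
from .omics import ExpressionMatrix

TIMEPOINTS = ("T0", "T1")

#: Per-cohort acquisition geometry. Patients use the four-b-value clinical
#: breast protocol on a coarser grid; PDX use the three-b-value preclinical
#: protocol on a finer grid.
COHORT_IMAGING = {
    "patient": {
        "b_values": (0.0, 100.0, 600.0, 800.0),
        "grid_shape": (28, 28, 12),
        "spacing": (1.0, 1.0, 2.0),
        "semi_axes": (10.0, 8.0, 6.0),
    },
    "PDX": {
        "b_values": (0.0, 150.0, 700.0),
        "grid_shape": (24, 24, 10),
        "spacing": (0.5, 0.5, 1.0),
        "semi_axes": (4.0, 3.0, 3.0),
    },
}

#: Dynamic frame grid: 25 frames every 30 s. The first 10 frames (0–270 s)
#: are pre-contrast baseline; the peak lands at 330 s so the 6-minute
#: post-peak frame (690 s) exists within the acquisition.
DCE_FRAME_TIMES = tuple(30.0 * i for i in range(25))
DCE_N_BASELINE = 10
_PEAK_FRAME = 11
_RISE_FRACTION = 0.6


@dataclass
class PhantomTruth:
    """Generating parameters for one synthetic subject."""

    subject_id: str
    cohort: str                                  # "patient" or "PDX"
    response_class: str                          # "responder" or "non-responder"
    volume_change_fraction: float                # (V_T1 - V_T0) / V_T0
    center_mm: np.ndarray
    semi_axes_mm: dict[str, np.ndarray]          # per timepoint
    adc_tumor: dict[str, float]                  # mm^2/s, per timepoint
    ser_tumor: dict[str, float]                  # per timepoint
    adc_background: float = 2.0e-3
    s0: float = 1000.0
    dce_baseline: float = 100.0
    dce_peak: float = 250.0
    noise_sigma_dwi: float = 0.0
    noise_sigma_dce: float = 0.0
    seed: int = 0


def digitize_ellipsoid(
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    grid_shape: Sequence[int],
    spacing: Sequence[float],
    label: str = "lesion",
) -> ROIMask:
    """Binary mask of voxel centers inside an axis-aligned ellipsoid."""
    center = np.asarray(center_mm, dtype=float)
    semi = np.asarray(semi_axes_mm, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    shape = tuple(int(s) for s in grid_shape)
    if np.any(semi <= 0):
        raise InvalidInputError("ellipsoid semi-axes must be positive")
    extent = (np.asarray(shape) - 1) * sp
    if np.any(center - semi < 0) or np.any(center + semi > extent):
        raise InvalidInputError(
            f"ellipsoid (center {center}, semi-axes {semi}) exceeds grid extent {extent}"
        )
    coords = [np.arange(shape[i]) * sp[i] for i in range(3)]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij")
    inside = (
        ((xs - center[0]) / semi[0]) ** 2
        + ((ys - center[1]) / semi[1]) ** 2
        + ((zs - center[2]) / semi[2]) ** 2
    ) <= 1.0
    return ROIMask(mask=inside, voxel_spacing=sp, label=label)


def make_dwi_phantom(
    truth: PhantomTruth,
    timepoint: str = "T0",
    b_values: Optional[Sequence[float]] = None,
    grid_shape: Optional[Sequence[int]] = None,
    spacing: Optional[Sequence[float]] = None,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
) -> tuple[DiffusionSeries, ROIMask]:
    """Diffusion series with monoexponential decay at the truth ADC.

    Tumor voxels decay at ``truth.adc_tumor[timepoint]``, background voxels at
    ``truth.adc_background``; optional additive Gaussian noise.
    """
    cfg = COHORT_IMAGING[truth.cohort]
    b = np.asarray(b_values if b_values is not None else cfg["b_values"], dtype=float)
    shape = tuple(grid_shape if grid_shape is not None else cfg["grid_shape"])
    sp = np.asarray(spacing if spacing is not None else cfg["spacing"], dtype=float)
    sigma = truth.noise_sigma_dwi if noise_sigma is None else noise_sigma
    mask = digitize_ellipsoid(
        truth.center_mm, truth.semi_axes_mm[timepoint], shape, sp,
        label=f"{truth.subject_id}-lesion",
    )
    adc = np.where(mask.mask, truth.adc_tumor[timepoint], truth.adc_background)
    signal = truth.s0 * np.exp(-adc[..., None] * b[None, None, None, :])
    if sigma > 0:
        rng = np.random.default_rng(
            truth.seed if seed is None else seed
        )
        signal = signal + rng.normal(0.0, sigma, size=signal.shape)
    return DiffusionSeries(voxels=signal, b_values=b, voxel_spacing=sp), mask


def _enhancement_curve(
    times: np.ndarray, baseline: float, peak: float, ser: float
) -> np.ndarray:
    """Piecewise tumor enhancement curve inverting to the prescribed SER.

    Flat baseline over the first 10 frames, a partial rise, the peak at frame
    11, then linear monotone washout through the level ``L`` at peak + 360 s
    chosen so that (peak - baseline) / (L - baseline) = ser.
    """
    late = baseline + (peak - baseline) / ser
    t_peak = times[_PEAK_FRAME]
    curve = np.full_like(times, baseline, dtype=float)
    curve[DCE_N_BASELINE] = baseline + _RISE_FRACTION * (peak - baseline)
    post = times >= t_peak
    curve[post] = peak + (late - peak) * (times[post] - t_peak) / 360.0
    return curve


def make_dce_phantom(
    truth: PhantomTruth,
    timepoint: str = "T0",
    frame_times: Optional[Sequence[float]] = None,
    grid_shape: Optional[Sequence[int]] = None,
    spacing: Optional[Sequence[float]] = None,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
) -> tuple[DynamicSeries, ROIMask]:
    """Dynamic series whose tumor voxels invert exactly to the truth SER.

    Background voxels never enhance (flat at the baseline level), so the SER
    map is NaN there by the denominator guard.
    """
    cfg = COHORT_IMAGING[truth.cohort]
    times = np.asarray(
        frame_times if frame_times is not None else DCE_FRAME_TIMES, dtype=float
    )
    if times[-1] < times[_PEAK_FRAME] + 360.0:
        raise InvalidInputError(
            "frame grid must extend at least 6 min past the peak frame"
        )
    shape = tuple(grid_shape if grid_shape is not None else cfg["grid_shape"])
    sp = np.asarray(spacing if spacing is not None else cfg["spacing"], dtype=float)
    sigma = truth.noise_sigma_dce if noise_sigma is None else noise_sigma
    mask = digitize_ellipsoid(
        truth.center_mm, truth.semi_axes_mm[timepoint], shape, sp,
        label=f"{truth.subject_id}-lesion",
    )
    curve = _enhancement_curve(
        times, truth.dce_baseline, truth.dce_peak, truth.ser_tumor[timepoint]
    )
    signal = np.where(
        mask.mask[..., None], curve[None, None, None, :], truth.dce_baseline
    )
    if sigma > 0:
        rng = np.random.default_rng(
            (truth.seed + 1) if seed is None else seed
        )
        signal = signal + rng.normal(0.0, sigma, size=signal.shape)
    return DynamicSeries(voxels=signal, frame_times=times, voxel_spacing=sp), mask


@dataclass
class CohortFixture:
    """A full synthetic co-clinical study: truths, expression, manifest."""

    subjects: list[PhantomTruth]
    expression: dict[str, ExpressionMatrix]          # T0 tables per cohort
    planted_up: list[str]
    planted_down: list[str]
    seed: int
    manifest: dict = field(default_factory=dict)

    def subjects_in(self, cohort: str) -> list[PhantomTruth]:
        return [s for s in self.subjects if s.cohort == cohort]

    def truth_volume_rr(self, cohort: str) -> pd.Series:
        """True percent volume change per subject, for association checks."""
        subs = self.subjects_in(cohort)
        return pd.Series(
            {s.subject_id: 100.0 * s.volume_change_fraction for s in subs}
        )


def make_cohort(
    n_patients: int = 21,
    n_pdx: int = 9,
    responder_fraction: float = 0.5,
    responder_volume_change: tuple[float, float] = (-0.6, -0.3),
    nonresponder_volume_change: tuple[float, float] = (-0.05, 0.25),
    n_genes: int = 2000,
    n_planted: int = 40,
    planted_effect: float = 4.0,
    planted_noise_sd: float = 0.8,
    noise_sigma_dwi: float = 20.0,
    noise_sigma_dce: float = 1.0,
    seed: int = 0,
) -> CohortFixture:
    """Generate a paired patient/PDX cohort with planted response biology.

    Responders' tumors shrink between T0 and T1 (volume change drawn from
    ``responder_volume_change``), their ADC rises (falling cellularity) and
    SER falls; non-responders hold steady or grow. Half the planted genes are
    positively, half negatively, coupled to the subject's volume change on
    the log scale with slope ``planted_effect`` and residual spread
    ``planted_noise_sd``; the same genes carry the signal in both cohorts so
    cross-cohort overlap is non-trivial. Fully reproducible from ``seed``.
    """
    if n_patients < 1 or n_pdx < 1:
        raise InvalidInputError("cohort sizes must be >= 1")
    if not 0 <= responder_fraction <= 1:
        raise InvalidInputError("responder_fraction must be in [0, 1]")
    if n_planted > n_genes:
        raise InvalidInputError("n_planted cannot exceed n_genes")

    root = np.random.SeedSequence(seed)
    ss_subjects, ss_genes = root.spawn(2)
    rng = np.random.default_rng(ss_subjects)

    subjects: list[PhantomTruth] = []
    for cohort, n_sub, prefix in (("patient", n_patients, "P"), ("PDX", n_pdx, "X")):
        cfg = COHORT_IMAGING[cohort]
        shape = np.asarray(cfg["grid_shape"])
        sp = np.asarray(cfg["spacing"])
        center = (shape - 1) * sp / 2.0
        semi_t0 = np.asarray(cfg["semi_axes"])
        n_resp = int(round(responder_fraction * n_sub))
        classes = ["responder"] * n_resp + ["non-responder"] * (n_sub - n_resp)
        for i in range(n_sub):
            cls = classes[i]
            lo, hi = (
                responder_volume_change if cls == "responder"
                else nonresponder_volume_change
            )
            vcf = float(rng.uniform(lo, hi))
            scale = (1.0 + vcf) ** (1.0 / 3.0)
            adc_t0 = float(rng.uniform(0.8e-3, 1.2e-3))
            ser_t0 = float(rng.uniform(1.8, 2.6))
            if cls == "responder":
                adc_t1 = adc_t0 * float(rng.uniform(1.2, 1.5))
                ser_t1 = max(1.05, ser_t0 * float(rng.uniform(0.6, 0.8)))
            else:
                adc_t1 = adc_t0 * float(rng.uniform(0.95, 1.05))
                ser_t1 = ser_t0 * float(rng.uniform(0.95, 1.05))
            subjects.append(
                PhantomTruth(
                    subject_id=f"{prefix}{i + 1:02d}",
                    cohort=cohort,
                    response_class=cls,
                    volume_change_fraction=vcf,
                    center_mm=center,
                    semi_axes_mm={"T0": semi_t0, "T1": semi_t0 * scale},
                    adc_tumor={"T0": adc_t0, "T1": adc_t1},
                    ser_tumor={"T0": ser_t0, "T1": ser_t1},
                    noise_sigma_dwi=noise_sigma_dwi,
                    noise_sigma_dce=noise_sigma_dce,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )

    # --- expression, shared gene panel across cohorts -----------------------
    grng = np.random.default_rng(ss_genes)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    planted_idx = grng.choice(n_genes, size=n_planted, replace=False)
    half = n_planted // 2
    up_idx, down_idx = planted_idx[:half], planted_idx[half:]
    beta = np.zeros(n_genes)
    beta[up_idx] = planted_effect
    beta[down_idx] = -planted_effect
    mu = grng.normal(4.0, 1.0, size=n_genes)

    expression: dict[str, ExpressionMatrix] = {}
    for cohort in ("patient", "PDX"):
        subs = [s for s in subjects if s.cohort == cohort]
        vcf = np.array([s.volume_change_fraction for s in subs])
        log_expr = (
            mu[:, None]
            + beta[:, None] * vcf[None, :]
            + grng.normal(0.0, planted_noise_sd, size=(n_genes, len(subs)))
        )
        values = pd.DataFrame(
            np.exp(log_expr), index=genes, columns=[s.subject_id for s in subs]
        )
        expression[cohort] = ExpressionMatrix(values, cohort=cohort, timepoint="T0")

    manifest = {
        "seed": seed,
        "n_patients": n_patients,
        "n_pdx": n_pdx,
        "timepoints": list(TIMEPOINTS),
        "studies": [
            {"subject_id": s.subject_id, "cohort": s.cohort, "timepoint": tp}
            for s in subjects
            for tp in TIMEPOINTS
        ],
    }
    return CohortFixture(
        subjects=subjects,
        expression=expression,
        planted_up=[genes[i] for i in sorted(up_idx)],
        planted_down=[genes[i] for i in sorted(down_idx)],
        seed=seed,
        manifest=manifest,
    )
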