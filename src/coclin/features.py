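"""Lesion-level imaging biomarkers.

From a binary tumor mask plus derived parameter maps, five scalar biomarkers
are extracted per lesion and timepoint: longest in-plane diameter (mm), tumor
volume (mm^3), and the mean/median of ADC and SER over valid tumor voxels.
A caliper-style volume (length x width^2 / 2) is provided for bench
measurements of engrafted tumors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import InvalidInputError
from .imaging import ParameterMap, ROIMask


@dataclass
class LesionFeatures:
    """Scalar biomarkers for one lesion at one timepoint."""

    subject_id: str
    lesion_label: str
    timepoint: str                      # "T0", "T1" or "T2"
    longest_diameter: float             # mm
    volume: float                       # mm^3
    adc_mean: float = np.nan            # mm^2/s
    adc_median: float = np.nan
    ser_mean: float = np.nan            # dimensionless
    ser_median: float = np.nan
    modality: str = "MR"
    study_date: str = ""

    FEATURE_NAMES = (
        "longest_diameter",
        "volume",
        "ser_mean",
        "ser_median",
        "adc_mean",
        "adc_median",
    )

    def value(self, feature_name: str) -> float:
        if feature_name not in self.FEATURE_NAMES:
            raise InvalidInputError(f"unknown feature {feature_name!r}")
        return getattr(self, feature_name)


def _max_pairwise(points: np.ndarray) -> float:
    """Maximum Euclidean distance between rows of ``points`` (n, 2)."""
    n = len(points)
    if n < 2:
        return 0.0
    # Convex hull prunes interior voxels for large slices; degenerate
    # (collinear) point sets fall back to the all-pairs scan.
    if n > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass
    return float(pdist(points).max())


def longest_diameter(mask: ROIMask, in_plane: bool = True) -> float:
    """Longest lesion diameter in mm, measured between voxel centers.

    By default the diameter is in-plane: for each axial slice (third array
    axis) the maximum pairwise distance among foreground voxel centers is
    taken, and the maximum over slices returned — the convention used for
    clinical diameter readings. ``in_plane=False`` measures over all three
    dimensions instead.
    """
    if mask.n_voxels == 0:
        raise InvalidInputError("cannot measure diameter of an empty mask")
    sp = mask.voxel_spacing
    if not in_plane:
        idx = np.argwhere(mask.mask).astype(float) * sp
        return _max_pairwise(idx) if len(idx) > 1 else 0.0
    best = 0.0
    for z in range(mask.mask.shape[2]):
        idx = np.argwhere(mask.mask[:, :, z]).astype(float)
        if len(idx) < 2:
            continue
        best = max(best, _max_pairwise(idx * sp[:2]))
    return best


def tumor_volume(mask: ROIMask) -> float:
    """Tumor volume in mm^3: foreground voxel count times voxel volume."""
    if mask.n_voxels == 0:
        raise InvalidInputError("cannot measure volume of an empty mask")
    return mask.n_voxels * float(np.prod(mask.voxel_spacing))


def roi_statistics(pmap: ParameterMap, mask: ROIMask) -> dict:
    """Mean/median of a parameter map over finite voxels inside the mask.

    Returns ``{"mean", "median", "n_valid"}``; an all-NaN ROI yields NaN
    statistics with ``n_valid == 0``.
    """
    if pmap.values.shape != mask.mask.shape:
        raise InvalidInputError(
            f"map shape {pmap.values.shape} does not match mask {mask.mask.shape}"
        )
    if mask.n_voxels == 0:
        raise InvalidInputError("cannot summarize an empty mask")
    vals = pmap.values[mask.mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return {"mean": np.nan, "median": np.nan, "n_valid": 0}
    return {
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "n_valid": int(len(vals)),
    }


def caliper_volume(length: float, width: float) -> float:
    """Caliper tumor volume, mm^3: length x width^2 x 0.5.

    The bench formula used to size engrafted tumors for randomization
    (typical enrollment threshold ~175 mm^3).
    """
    if length <= 0 or width <= 0:
        raise InvalidInputError("length and width must be positive")
    if length < width:
        raise InvalidInputError("length must be >= width")
    return length * width**2 * 0.5


def extract_lesion_features(
    mask: ROIMask,
    adc_map: Optional[ParameterMap] = None,
    ser_map: Optional[ParameterMap] = None,
    subject_id: str = "",
    timepoint: str = "T0",
    modality: str = "MR",
    study_date: str = "",
) -> LesionFeatures:
    """Bundle all per-lesion biomarkers for one mask and its maps."""
    feats = LesionFeatures(
        subject_id=subject_id,
        lesion_label=mask.label,
        timepoint=timepoint,
        longest_diameter=longest_diameter(mask),
        volume=tumor_volume(mask),
        modality=modality,
        study_date=study_date,
    )
    if adc_map is not None:
        st = roi_statistics(adc_map, mask)
        feats.adc_mean, feats.adc_median = st["mean"], st["median"]
    if ser_map is not None:
        st = roi_statistics(ser_map, mask)
        feats.ser_mean, feats.ser_median = st["mean"], st["median"]
    return feats
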