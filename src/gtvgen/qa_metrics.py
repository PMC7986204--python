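"""Automated failure gates, motion amplitude, and contour validation metrics.

Two automated checks mirror large-cohort practice: a registration gate on
the correlation-ratio cost statistics (mean < 0.73 or SD >= 0.13 fails), and
an iGTV volume-ratio check on the generated contour (ratio < 0.84 routes the
case to visual "check"; at or above, it can be trusted without review).
Validation against an expert reference uses directed surface
distance-to-agreement (DTA), the volume ratio, and the distance between
centres of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import EmptyMaskError, GridMismatchError
from .imaging_io import BinaryMask
from .registration import MotionPath


@dataclass(frozen=True)
class QAThresholds:
    """Gate thresholds; defaults are the standard clinical operating points."""

    cost_mean_min: float = 0.73  # fail below
    cost_sd_max: float = 0.13  # fail at or above
    ratio_check: float = 0.84  # "check" below, "trust" at or above


@dataclass
class QAReport:
    """Automated assessment of one GTV generation run."""

    cost_mean: float
    cost_sd: float
    registration_pass: bool
    generation_failed: bool
    igtv_ratio: Optional[float]
    category: str  # trust | check | fail
    amplitude_mm: float
    method_id: Optional[int] = None
    volumes_cc: dict = field(default_factory=dict)
    manual_override: Optional[str] = None  # optional human pass/fail rating


@dataclass
class ValidationReport:
    """Generated-vs-reference contour comparison."""

    dta_mean_mm: float
    dta_sd_mm: float
    volume_ratio: float
    com_distance_mm: float


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------


def classify_registration(
    cost_mean: float, cost_sd: float, thresholds: QAThresholds = QAThresholds()
) -> bool:
    """True iff the registration passes the cost gate.

    Fails iff ``cost_mean < 0.73`` or ``cost_sd >= 0.13`` (inclusive bound).
    """
    return not (cost_mean < thresholds.cost_mean_min or cost_sd >= thresholds.cost_sd_max)


def classify_contour(
    igtv_ratio: float, thresholds: QAThresholds = QAThresholds()
) -> str:
    """Route a generated contour: "check" iff the ratio is below 0.84."""
    return "check" if igtv_ratio < thresholds.ratio_check else "trust"


def assemble_report(
    cost_mean: float,
    cost_sd: float,
    generation_failed: bool,
    igtv_ratio: Optional[float],
    amplitude_mm: float,
    method_id: Optional[int] = None,
    volumes_cc: Optional[dict] = None,
    thresholds: QAThresholds = QAThresholds(),
) -> QAReport:
    """Combine the gates into the final trust / check / fail category."""
    reg_pass = classify_registration(cost_mean, cost_sd, thresholds)
    if not reg_pass or generation_failed or igtv_ratio is None:
        category = "fail"
    else:
        category = classify_contour(igtv_ratio, thresholds)
    return QAReport(
        cost_mean=cost_mean,
        cost_sd=cost_sd,
        registration_pass=reg_pass,
        generation_failed=generation_failed,
        igtv_ratio=igtv_ratio,
        category=category,
        amplitude_mm=amplitude_mm,
        method_id=method_id,
        volumes_cc=volumes_cc or {},
    )


# ---------------------------------------------------------------------------
# Motion amplitude
# ---------------------------------------------------------------------------


def motion_amplitude(path: MotionPath) -> float:
    """Peak-to-peak positional range per axis, combined as a vector norm."""
    arr = path.as_array()
    ranges = arr.max(axis=0) - arr.min(axis=0)
    return float(np.linalg.norm(ranges))


# ---------------------------------------------------------------------------
# Surface metrics
# ---------------------------------------------------------------------------


def surface_points_mm(mask: BinaryMask) -> np.ndarray:
    """Centres (mm) of the boundary voxels (6-connectivity surface)."""
    if mask.is_empty:
        raise EmptyMaskError("an empty mask has no surface")
    cross = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.voxels, structure=cross)
    boundary = mask.voxels & ~interior
    return mask.geometry.index_to_mm(np.argwhere(boundary))


def surface_dta(test: BinaryMask, reference: BinaryMask) -> Tuple[float, float]:
    """Directed distance-to-agreement, test surface -> reference surface.

    For every surface point of ``test``, the Euclidean distance to the
    nearest surface point of ``reference``; returns (mean, SD) across the
    test surface. Directed: DTA(a, b) generally differs from DTA(b, a).
    """
    if test.geometry != reference.geometry:
        raise GridMismatchError("DTA requires a common grid")
    pts_test = surface_points_mm(test)
    pts_ref = surface_points_mm(reference)
    d, _ = cKDTree(pts_ref).query(pts_test)
    return float(np.mean(d)), float(np.std(d))


def com_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Euclidean distance (mm) between unweighted true-voxel centroids."""
    return float(np.linalg.norm(a.centroid_mm() - b.centroid_mm()))


def hausdorff_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance (mm) between boundary-voxel surfaces."""
    pa, pb = surface_points_mm(a), surface_points_mm(b)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    return float(max(d_ab.max(), d_ba.max()))


def validate(gen: BinaryMask, reference: BinaryMask) -> ValidationReport:
    """DTA (gen -> reference), volume ratio gen/reference, CoM distance."""
    if gen.geometry != reference.geometry:
        raise GridMismatchError("validation requires a common grid")
    if reference.is_empty or gen.is_empty:
        raise EmptyMaskError("validation requires non-empty masks")
    mean, sd = surface_dta(gen, reference)
    return ValidationReport(
        dta_mean_mm=mean,
        dta_sd_mm=sd,
        volume_ratio=gen.volume_cc / reference.volume_cc,
        com_distance_mm=com_distance(gen, reference),
    )
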