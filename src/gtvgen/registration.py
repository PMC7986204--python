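"""Per-phase tumor translation estimation on 4D-CT.

The tumor is treated as a rigid body: rotation and deformation over the
breathing cycle are small compared to translation, so each phase is mapped
onto the reference phase (50%) by a pure 3D translation. Registration is
restricted to a volume of interest (VOI) around the delineated iGTV, uses
the correlation-ratio cost (0..1, 1 = perfect functional dependence of the
moving image's intensities on the fixed image's), visits the phases in a
cyclic order with prematching, and is repeated for four VOI strategies; the
strategy with the most consistent cost (minimum SD) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import (
    EmptyMaskError,
    GridMismatchError,
    NoValidRegistrationError,
    ParameterError,
    RegistrationFailure,
    UndefinedCostError,
)
from .imaging_io import (
    DEFAULT_REFERENCE,
    PHASE_LABELS,
    BinaryMask,
    GridGeometry,
    ImageVolume,
    PhaseSeries,
)

#: HU threshold above which voxels are treated as bone/cartilage (chest wall).
CHEST_WALL_HU: float = 176.0


class Translation(NamedTuple):
    """A 3D shift in mm along the (LR, AP, SI) axes."""

    dx_lr: float = 0.0
    dy_ap: float = 0.0
    dz_si: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    @classmethod
    def from_array(cls, arr) -> "Translation":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,):
            raise ParameterError(f"a translation has 3 components, got {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))


@dataclass
class MotionPath:
    """Per-phase translations with a zero entry at the reference phase.

    Used in two roles with the same container: the *forward* trajectory
    (offset of the tumor at each phase relative to the reference) and the
    *reverse* path estimated by registration (the translation mapping each
    phase's tumor onto the reference). One is the negation of the other.
    """

    shifts: Dict[int, Translation]
    reference_label: int = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        self.shifts = {
            int(k): (v if isinstance(v, Translation) else Translation.from_array(v))
            for k, v in self.shifts.items()
        }
        if tuple(sorted(self.shifts)) != PHASE_LABELS:
            raise ParameterError(f"a motion path has exactly the phases {PHASE_LABELS}")
        ref = self.shifts[self.reference_label]
        if ref.norm > 1e-9:
            raise ParameterError("the reference-phase shift must be zero")

    def as_array(self) -> np.ndarray:
        """(10, 3) array of shifts in phase-label order 0%..90%."""
        return np.array([self.shifts[k] for k in PHASE_LABELS], dtype=float)

    def negated(self) -> "MotionPath":
        return MotionPath(
            {k: Translation.from_array(-t.as_array()) for k, t in self.shifts.items()},
            self.reference_label,
        )

    @classmethod
    def from_array(
        cls, offsets, reference_label: int = DEFAULT_REFERENCE
    ) -> "MotionPath":
        offsets = np.asarray(offsets, dtype=float)
        if offsets.shape != (10, 3):
            raise ParameterError("expected a (10, 3) offset array")
        return cls(
            {k: Translation.from_array(offsets[i]) for i, k in enumerate(PHASE_LABELS)},
            reference_label,
        )


@dataclass(frozen=True)
class VOIMethod:
    """One of the four VOI strategies for the phase registrations.

    1. iGTV + 4 mm spherical expansion;
    2. as 1 with the chest wall (closed >176 HU set) removed;
    3. as 1 with a prior SI translation following 2 cm peak-peak breathing;
    4. iGTV + 10 mm total expansion, for mobile low-contrast tumors.
    """

    id: int
    expansion_mm: float
    chest_wall_removed: bool
    si_prior_peak_peak_mm: float

    @classmethod
    def standard(cls, method_id: int) -> "VOIMethod":
        table = {
            1: cls(1, 4.0, False, 0.0),
            2: cls(2, 4.0, True, 0.0),
            3: cls(3, 4.0, False, 20.0),
            4: cls(4, 10.0, False, 0.0),
        }
        try:
            return table[method_id]
        except KeyError:
            raise ParameterError(f"unknown VOI method id {method_id}") from None


STANDARD_VOI_METHODS: Tuple[VOIMethod, ...] = tuple(
    VOIMethod.standard(i) for i in (1, 2, 3, 4)
)


@dataclass
class SearchSettings:
    """Deterministic coarse-to-fine grid-search parameters (all mm)."""

    coarse_step_mm: float = 2.0
    coarse_halfwidth_mm: float = 8.0
    refine_steps_mm: Tuple[float, ...] = (1.0, 0.5, 0.25)
    refine_halfsteps: int = 2
    search_radius_mm: float = 25.0
    n_bins: int = 32
    min_bin_count: int = 5


@dataclass
class RegistrationOutcome:
    """Translations + correlation-ratio costs for one VOI method."""

    method: VOIMethod
    path: MotionPath
    costs: Dict[int, float]
    failed: bool = False
    failure_reason: str = ""

    @property
    def cost_values(self) -> np.ndarray:
        return np.array([self.costs[k] for k in sorted(self.costs)], dtype=float)

    @property
    def cost_mean(self) -> float:
        return float(np.mean(self.cost_values))

    @property
    def cost_sd(self) -> float:
        # sample SD over the nine phase registrations
        return float(np.std(self.cost_values, ddof=1))


# ---------------------------------------------------------------------------
# VOI construction
# ---------------------------------------------------------------------------


def ball_footprint(geometry: GridGeometry, radius_mm: float) -> np.ndarray:
    """Boolean structuring element: voxel-centre offsets within radius_mm."""
    r = np.maximum(np.floor(radius_mm / np.array(geometry.spacing)).astype(int), 0)
    ax = [np.arange(-n, n + 1) * s for n, s in zip(r, geometry.spacing)]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    return dx**2 + dy**2 + dz**2 <= radius_mm**2 + 1e-9


def build_voi(
    igtv: BinaryMask, reference_image: ImageVolume, method: VOIMethod
) -> BinaryMask:
    """iGTV dilated by the method's spherical margin, minus chest wall if asked."""
    if igtv.is_empty:
        raise EmptyMaskError("cannot build a VOI from an empty iGTV")
    if igtv.geometry != reference_image.geometry:
        raise GridMismatchError("iGTV and reference image must share a grid")
    if method.expansion_mm > 0:
        footprint = ball_footprint(igtv.geometry, method.expansion_mm)
        voxels = ndimage.binary_dilation(igtv.voxels, structure=footprint)
    else:
        voxels = igtv.voxels.copy()
    voi = BinaryMask(igtv.geometry, voxels)
    if method.chest_wall_removed:
        voi = remove_chest_wall(reference_image, voi)
    return voi


def remove_chest_wall(
    image: ImageVolume, voi: BinaryMask, closing_radius_mm: float = 5.0
) -> BinaryMask:
    """Subtract the morphologically closed >176 HU (bone/cartilage) set."""
    if image.geometry != voi.geometry:
        raise GridMismatchError("image and VOI must share a grid")
    bone = image.values > CHEST_WALL_HU
    if not bone.any():
        return BinaryMask(voi.geometry, voi.voxels.copy())
    footprint = ball_footprint(image.geometry, closing_radius_mm)
    # pad so the closing's erosion does not eat structures at the array edge
    pad = [(n // 2,) * 2 for n in footprint.shape]
    closed = ndimage.binary_closing(
        np.pad(bone, pad, mode="edge"), structure=footprint
    )
    closed = closed[tuple(slice(p, -p if p else None) for p, _ in pad)]
    return BinaryMask(voi.geometry, voi.voxels & ~closed)


# ---------------------------------------------------------------------------
# Correlation-ratio cost
# ---------------------------------------------------------------------------


def _correlation_ratio_1d(
    fixed: np.ndarray,
    moving: np.ndarray,
    n_bins: int = 32,
    min_bin_count: int = 5,
) -> float:
    """eta^2 = 1 - E[Var(moving | fixed bin)] / Var(moving), clipped to [0, 1].

    Fixed intensities are partitioned into ``n_bins`` equal-width bins over
    their range; bins holding fewer than ``min_bin_count`` voxels are dropped
    (their voxels excluded from both terms) for stability on small VOIs.
    With finite-width bins, exact functional dependence scores slightly
    below 1 (residual within-bin variance of order bin width squared).
    """
    fixed = np.asarray(fixed, dtype=float).ravel()
    moving = np.asarray(moving, dtype=float).ravel()
    lo, hi = fixed.min(), fixed.max()
    if hi <= lo:
        raise UndefinedCostError("fixed image constant inside the mask")
    bins = np.minimum(
        ((fixed - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1
    )
    counts = np.bincount(bins, minlength=n_bins)
    keep_bin = counts >= min_bin_count
    if keep_bin.sum() < 2:
        raise UndefinedCostError("fewer than two populated fixed-intensity bins")
    keep = keep_bin[bins]
    b, m = bins[keep], moving[keep]
    cnt = np.bincount(b, minlength=n_bins).astype(float)
    s = np.bincount(b, weights=m, minlength=n_bins)
    ss = np.bincount(b, weights=m * m, minlength=n_bins)
    n = m.size
    total_var = ss.sum() / n - (s.sum() / n) ** 2
    if total_var <= 0:
        raise UndefinedCostError("moving image has no variance inside the mask")
    with np.errstate(invalid="ignore", divide="ignore"):
        within = np.where(cnt > 0, ss - s * s / np.where(cnt > 0, cnt, 1), 0.0)
    eta2 = 1.0 - within.sum() / n / total_var
    return float(np.clip(eta2, 0.0, 1.0))


def correlation_ratio(
    fixed: ImageVolume,
    moving: ImageVolume,
    mask: BinaryMask,
    n_bins: int = 32,
    min_bin_count: int = 5,
) -> float:
    """Correlation ratio of ``moving`` on ``fixed`` over the masked voxels."""
    if not (fixed.geometry == moving.geometry == mask.geometry):
        raise GridMismatchError("fixed, moving and mask must share a grid")
    if mask.is_empty:
        raise EmptyMaskError("correlation ratio over an empty mask")
    sel = mask.voxels
    return _correlation_ratio_1d(
        fixed.values[sel], moving.values[sel], n_bins, min_bin_count
    )


# ---------------------------------------------------------------------------
# Translation-only registration
# ---------------------------------------------------------------------------


class _CostEvaluator:
    """Correlation-ratio cost of a candidate translation over a fixed VOI.

    The fixed image's bin assignment inside the VOI is computed once; each
    candidate only resamples the moving image (trilinear) at the VOI voxel
    centres offset by the candidate and accumulates per-bin variances.
    """

    def __init__(
        self,
        fixed: ImageVolume,
        moving: ImageVolume,
        voi: BinaryMask,
        settings: SearchSettings,
    ) -> None:
        if not (fixed.geometry == moving.geometry == voi.geometry):
            raise GridMismatchError("fixed, moving and VOI must share a grid")
        if voi.is_empty:
            raise EmptyMaskError("registration VOI is empty")
        self.settings = settings
        self.moving = np.asarray(moving.values, dtype=float)
        self.spacing = np.array(fixed.geometry.spacing)
        idx = np.argwhere(voi.voxels)
        fvals = np.asarray(fixed.values, dtype=float)[voi.voxels]
        lo, hi = fvals.min(), fvals.max()
        if hi <= lo:
            raise UndefinedCostError("fixed image constant inside the VOI")
        n_bins = settings.n_bins
        bins = np.minimum(((fvals - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        counts = np.bincount(bins, minlength=n_bins)
        keep_bin = counts >= settings.min_bin_count
        if keep_bin.sum() < 2:
            raise UndefinedCostError("fewer than two populated fixed-intensity bins")
        keep = keep_bin[bins]
        self.bins = bins[keep]
        self.idx = idx[keep].T.astype(float)  # (3, n) voxel indices
        self.n = self.bins.size
        self.n_bins = n_bins

    def cost(self, t: np.ndarray) -> float:
        """Cost of shifting the moving image by ``t`` (mm) onto the fixed."""
        # content moved by +t  <=>  sample moving at x - t
        coords = self.idx - (np.asarray(t, dtype=float) / self.spacing)[:, None]
        m = ndimage.map_coordinates(self.moving, coords, order=1, mode="nearest")
        cnt = np.bincount(self.bins, minlength=self.n_bins).astype(float)
        s = np.bincount(self.bins, weights=m, minlength=self.n_bins)
        ss = np.bincount(self.bins, weights=m * m, minlength=self.n_bins)
        total_var = ss.sum() / self.n - (s.sum() / self.n) ** 2
        if total_var <= 0:
            return np.nan
        within = np.where(cnt > 0, ss - s * s / np.where(cnt > 0, cnt, 1), 0.0)
        return float(np.clip(1.0 - within.sum() / self.n / total_var, 0.0, 1.0))


def _axis_offsets(step: float, halfwidth: float) -> np.ndarray:
    n = int(round(halfwidth / step))
    return step * np.arange(-n, n + 1)


def register_translation(
    fixed: ImageVolume,
    moving: ImageVolume,
    voi: BinaryMask,
    init: Translation = Translation(),
    settings: Optional[SearchSettings] = None,
) -> Tuple[Translation, float]:
    """Find the translation maximising the correlation ratio over the VOI.

    Deterministic coarse-to-fine grid search: a 2 mm grid centred on ``init``
    followed by refinement levels down to 0.25 mm around the incumbent, with
    trilinear interpolation of the moving image. The seeded initial point is
    always a candidate, so refinement cannot worsen a seeded optimum.
    """
    settings = settings or SearchSettings()
    evaluator = _CostEvaluator(fixed, moving, voi, settings)
    init_arr = np.asarray(init, dtype=float)
    radius = settings.search_radius_mm

    def admissible(t: np.ndarray) -> bool:
        return float(np.linalg.norm(t)) <= radius + 1e-9

    best_t, best_c = None, -np.inf
    offsets = _axis_offsets(settings.coarse_step_mm, settings.coarse_halfwidth_mm)
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                t = init_arr + (dx, dy, dz)
                if not admissible(t):
                    continue
                c = evaluator.cost(t)
                if np.isfinite(c) and c > best_c:
                    best_t, best_c = t, c
    if best_t is None:
        raise RegistrationFailure("cost undefined at every coarse candidate")
    for step in settings.refine_steps_mm:
        offsets = step * np.arange(
            -settings.refine_halfsteps, settings.refine_halfsteps + 1
        )
        center = best_t
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    t = center + (dx, dy, dz)
                    if not admissible(t):
                        continue
                    c = evaluator.cost(t)
                    if np.isfinite(c) and c > best_c:
                        best_t, best_c = t, c
    return Translation.from_array(best_t), best_c


# ---------------------------------------------------------------------------
# Cyclic per-phase registration and method selection
# ---------------------------------------------------------------------------


def cyclic_phase_order(reference_label: int = DEFAULT_REFERENCE) -> List[int]:
    """Phases visited from the reference, wrapping 90% -> 0%."""
    i0 = PHASE_LABELS.index(reference_label)
    return [PHASE_LABELS[(i0 + j) % 10] for j in range(1, 10)]


def si_prior_mm(phase_label: int, peak_peak_mm: float) -> float:
    """Prior SI translation for a phase: raised cosine, zero at the reference.

    ``P/2 * (1 + cos(2 pi k / 10))`` with k the phase index — maximal at the
    0% inhale peak, zero at 50%.
    """
    k = phase_label / 10.0
    return peak_peak_mm / 2.0 * (1.0 + np.cos(2.0 * np.pi * k / 10.0))


def cyclic_register(
    series: PhaseSeries,
    voi: BinaryMask,
    method: VOIMethod,
    settings: Optional[SearchSettings] = None,
) -> RegistrationOutcome:
    """Register every non-reference phase onto the reference, cyclically.

    Each registration is initialised at the previous phase's result
    (prematching); for method 3 the SI prior increment between consecutive
    phases is added to the initialisation.
    """
    settings = settings or SearchSettings()
    ref_label = series.reference_label
    fixed = series.reference
    shifts: Dict[int, Translation] = {ref_label: Translation()}
    costs: Dict[int, float] = {}
    prev_result = np.zeros(3)
    prev_label = ref_label
    P = method.si_prior_peak_peak_mm
    for label in cyclic_phase_order(ref_label):
        init = prev_result.copy()
        if P > 0:
            init[2] += si_prior_mm(label, P) - si_prior_mm(prev_label, P)
        try:
            t, c = register_translation(
                fixed, series.phases[label], voi, Translation.from_array(init), settings
            )
        except (RegistrationFailure, UndefinedCostError) as exc:
            return RegistrationOutcome(
                method=method,
                path=MotionPath(
                    {k: shifts.get(k, Translation()) for k in PHASE_LABELS}, ref_label
                ),
                costs={k: 0.0 for k in PHASE_LABELS if k != ref_label},
                failed=True,
                failure_reason=f"phase {label}%: {exc}",
            )
        shifts[label] = t
        costs[label] = c
        prev_result = t.as_array()
        prev_label = label
    return RegistrationOutcome(
        method=method, path=MotionPath(shifts, ref_label), costs=costs
    )


def select_registration(
    outcomes: Sequence[RegistrationOutcome],
) -> RegistrationOutcome:
    """Pick the outcome with minimal cost SD; ties go to the lower method id."""
    valid = [o for o in outcomes if not o.failed]
    if not valid:
        raise NoValidRegistrationError("all VOI-method registrations failed")
    return min(valid, key=lambda o: (o.cost_sd, o.method.id))
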