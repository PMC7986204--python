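"""Synthetic lung 4D-CT phantoms with known tumor motion and ground truth.

Each phantom is a ten-phase CT series: low-density lung parenchyma, a
higher-density tumor translated rigidly along a per-phase trajectory
(raised-cosine SI waveform with optional AP hysteresis loop, or explicit
per-phase offsets), an optional high-density chest-wall slab, CT-like blur
and Gaussian noise. The ground-truth tumor mask at the reference phase, the
exact motion-envelope iGTV, and the reverse motion path come along, so every
downstream stage is testable without patient data.

Default HU palette: lung -800, tumor +20, chest wall +300, noise SD 20 HU —
values that straddle the 176 HU bone/cartilage threshold realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import BoundsError, DegenerateMaskError, ParameterError
from .imaging_io import (
    DEFAULT_REFERENCE,
    PHASE_LABELS,
    BinaryMask,
    GridGeometry,
    ImageVolume,
    PhaseSeries,
)
from .registration import MotionPath, Translation, ball_footprint

DEFAULT_GRID = GridGeometry(shape=(96, 96, 40), spacing=(1.17, 1.17, 3.0))


@dataclass
class PhantomConfig:
    """Parameters of one synthetic 4D-CT phantom.

    ``trajectory`` may give explicit (10, 3) per-phase forward offsets in mm
    (reference entry zero); otherwise a raised-cosine SI waveform with
    peak-to-peak amplitude ``peak_to_peak_mm`` along ``si_direction`` and an
    AP hysteresis loop of width ``hysteresis_mm`` is used. Defaults emulate a
    routinely observed mid-range lung tumor: 10 mm peak-to-peak SI motion
    (clinical means sit near 7 mm), 2 mm hysteresis, 10 mm tumor radius.
    """

    grid: GridGeometry = field(default_factory=lambda: DEFAULT_GRID)
    shape_kind: str = "sphere"  # sphere | ellipsoid | lobulated
    radius_mm: float = 10.0
    semi_axes_mm: Tuple[float, float, float] = (10.0, 8.0, 6.0)
    lobulation_amplitude: float = 0.25  # fractional radial bump size
    lobulation_lobes: int = 3
    center_mm: Optional[Tuple[float, float, float]] = None  # default: grid centre
    trajectory: Optional[np.ndarray] = None  # explicit (10, 3) forward offsets
    peak_to_peak_mm: float = 10.0
    hysteresis_mm: float = 2.0
    si_direction: float = 1.0  # +1: towards +SI at inhale; sign configurable
    tumor_hu: float = 20.0
    lung_hu: float = -800.0
    chestwall_hu: float = 300.0
    chest_wall: bool = True
    chest_wall_thickness_mm: float = 9.0
    blur_sigma_mm: float = 1.2  # CT point-spread emulation
    noise_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_hu < 0:
            raise ParameterError("noise SD must be non-negative")
        if self.trajectory is not None:
            self.trajectory = np.asarray(self.trajectory, dtype=float)
            if self.trajectory.shape != (10, 3):
                raise ParameterError("explicit trajectory must be (10, 3)")
            iref = PHASE_LABELS.index(DEFAULT_REFERENCE)
            if np.linalg.norm(self.trajectory[iref]) > 1e-9:
                raise ParameterError("the reference-phase offset must be zero")

    @property
    def center(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=float)
        g = self.grid
        return g.index_to_mm((np.array(g.shape, dtype=float) - 1) / 2.0)


@dataclass
class GroundTruth:
    """What the phantom knows and the pipeline must recover."""

    gtv_true: BinaryMask
    igtv_true: BinaryMask
    path_true: MotionPath  # reverse path: phase -> reference translations
    amplitude_true: float


# ---------------------------------------------------------------------------
# Tumor shape
# ---------------------------------------------------------------------------


def _shape_indicator(config: PhantomConfig, points: np.ndarray) -> np.ndarray:
    """True for points (…, 3) in mm inside the tumor centred at the origin."""
    p = np.asarray(points, dtype=float)
    if config.shape_kind == "sphere":
        return (p**2).sum(axis=-1) <= config.radius_mm**2
    if config.shape_kind == "ellipsoid":
        a = np.asarray(config.semi_axes_mm, dtype=float)
        return ((p / a) ** 2).sum(axis=-1) <= 1.0
    if config.shape_kind == "lobulated":
        r = np.sqrt((p**2).sum(axis=-1))
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(np.divide(p[..., 2], np.where(r > 0, r, 1)), -1, 1))
        phi = np.arctan2(p[..., 1], p[..., 0])
        n = config.lobulation_lobes
        bump = np.cos(n * theta) * np.sin(n * phi)  # smooth radial lobes
        radius = config.radius_mm * (1.0 + config.lobulation_amplitude * bump)
        return r <= radius
    raise ParameterError(f"unknown shape_kind {config.shape_kind!r}")


def _max_shape_radius(config: PhantomConfig) -> float:
    if config.shape_kind == "sphere":
        return config.radius_mm
    if config.shape_kind == "ellipsoid":
        return float(max(config.semi_axes_mm))
    return config.radius_mm * (1.0 + abs(config.lobulation_amplitude))


def _voxel_centers(grid: GridGeometry) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    return x, y, z


def _indicator_on_grid(
    config: PhantomConfig, offset_mm: np.ndarray = np.zeros(3)
) -> np.ndarray:
    """Voxel-centre inside-test of the tumor shifted by ``offset_mm``."""
    x, y, z = _voxel_centers(config.grid)
    c = config.center + np.asarray(offset_mm, dtype=float)
    pts = np.stack(
        np.broadcast_arrays(x - c[0], y - c[1], z - c[2]), axis=-1
    )
    return _shape_indicator(config, pts)


def _check_bounds(config: PhantomConfig, offsets: np.ndarray) -> None:
    g = config.grid
    lo = np.array(g.origin) - np.array(g.spacing) / 2.0
    hi = lo + np.array(g.spacing) * np.array(g.shape)
    r = _max_shape_radius(config)
    for d in np.atleast_2d(offsets):
        c = config.center + d
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise BoundsError(
                "tumor (with trajectory margin) does not fit inside the grid"
            )


def make_tumor_shape(config: PhantomConfig) -> BinaryMask:
    """Voxelise the tumor at the reference position (trajectory offset zero)."""
    offsets = forward_offsets(config)
    _check_bounds(config, offsets)
    return BinaryMask(config.grid, _indicator_on_grid(config))


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


def forward_offsets(config: PhantomConfig) -> np.ndarray:
    """(10, 3) forward offsets in mm of the tumor at each phase vs reference.

    Default waveform: ``d_SI(k) = A/2 * (1 + cos(2 pi k / 10))`` — maximal at
    the 0% inhale peak, zero at the 50% reference — plus an elliptical AP
    hysteresis component ``d_AP(k) = h/2 * sin(2 pi k / 10)``.
    """
    if config.trajectory is not None:
        return config.trajectory.copy()
    k = np.arange(10, dtype=float)
    theta = 2.0 * np.pi * k / 10.0
    d = np.zeros((10, 3))
    d[:, 2] = config.si_direction * config.peak_to_peak_mm / 2.0 * (1.0 + np.cos(theta))
    d[:, 1] = config.hysteresis_mm / 2.0 * np.sin(theta)
    return d


def make_trajectory(config: PhantomConfig) -> MotionPath:
    """Forward per-phase offsets as a MotionPath (reference entry zero)."""
    return MotionPath.from_array(forward_offsets(config), DEFAULT_REFERENCE)


def _densified_offsets(offsets: np.ndarray, step_mm: float) -> np.ndarray:
    """Sample the piecewise-linear polyline through ``offsets`` every <=step_mm."""
    if step_mm <= 0:
        raise ParameterError("densification step must be positive")
    samples = [offsets[0]]
    for a, b in zip(offsets[:-1], offsets[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step_mm)))
        for i in range(1, n + 1):
            samples.append(a + (b - a) * i / n)
    return np.array(samples)


# ---------------------------------------------------------------------------
# Envelope union
# ---------------------------------------------------------------------------


def build_envelope_union(
    shape: BinaryMask, path: MotionPath, step_mm: float = 0.5
) -> BinaryMask:
    """Union of ``shape`` swept along the densified piecewise-linear path.

    ``path`` holds forward offsets (phase order 0%..90%); each sampled offset
    is applied by per-axis nearest-neighbour (rounded-voxel) shifting.
    """
    offsets = _densified_offsets(path.as_array(), step_mm)
    spacing = np.array(shape.geometry.spacing)
    steps = np.unique(np.round(offsets / spacing).astype(int), axis=0)
    out = np.zeros_like(shape.voxels)
    for s in steps:
        out |= _integer_shift(shape.voxels, s)
    return BinaryMask(shape.geometry, out)


def _integer_shift(voxels: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Shift a boolean array by whole voxels, dropping content at the edges."""
    out = np.zeros_like(voxels)
    src = []
    dst = []
    for n, step in zip(voxels.shape, steps):
        step = int(step)
        if abs(step) >= n:
            return out
        if step >= 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    out[tuple(dst)] = voxels[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# Phase-series rendering
# ---------------------------------------------------------------------------


def _analytic_envelope(config: PhantomConfig, step_mm: float = 0.5) -> np.ndarray:
    """Voxel-centre inside-test of the continuously swept tumor.

    Emulates an observer contouring the true motion envelope slice by slice:
    a voxel is true iff its centre lies inside the tumor at *some* instant of
    the densified trajectory.
    """
    offsets = _densified_offsets(forward_offsets(config), step_mm)
    out = np.zeros(config.grid.shape, dtype=bool)
    for d in offsets:
        out |= _indicator_on_grid(config, d)
    return out


def render_phase_series(config: PhantomConfig) -> Tuple[PhaseSeries, GroundTruth]:
    """Render the ten phase volumes and the phantom's ground truth.

    Identical configs (same seed) render bit-identical series.
    """
    offsets = forward_offsets(config)
    _check_bounds(config, offsets)
    g = config.grid
    rng = np.random.default_rng(config.seed)
    sigma_vox = config.blur_sigma_mm / np.array(g.spacing)

    wall = np.zeros(g.shape, dtype=bool)
    if config.chest_wall:
        y = g.axis_coords(1)
        n_wall = int(np.sum(y > y[-1] - config.chest_wall_thickness_mm))
        if n_wall > 0:
            wall[:, -n_wall:, :] = True

    phases: Dict[int, ImageVolume] = {}
    for i, label in enumerate(PHASE_LABELS):
        tumor = _indicator_on_grid(config, offsets[i])
        field_hu = np.full(g.shape, config.lung_hu, dtype=float)
        field_hu[wall] = config.chestwall_hu
        field_hu[tumor] = config.tumor_hu
        if config.blur_sigma_mm > 0:
            field_hu = ndimage.gaussian_filter(field_hu, sigma=sigma_vox)
        if config.noise_sd_hu > 0:
            field_hu = field_hu + rng.normal(0.0, config.noise_sd_hu, size=g.shape)
        phases[label] = ImageVolume(g, field_hu.astype(np.float32))

    gtv_true = BinaryMask(g, _indicator_on_grid(config))
    igtv_true = BinaryMask(g, _analytic_envelope(config))
    path_true = MotionPath.from_array(-offsets, DEFAULT_REFERENCE)  # reverse path
    ranges = offsets.max(axis=0) - offsets.min(axis=0)
    amplitude = float(np.linalg.norm(ranges))
    series = PhaseSeries(phases, DEFAULT_REFERENCE)
    return series, GroundTruth(gtv_true, igtv_true, path_true, amplitude)


# ---------------------------------------------------------------------------
# Randomized phantom family
# ---------------------------------------------------------------------------


def sample_phantom_config(
    rng: np.random.Generator,
    amplitude_mm: Optional[float] = None,
    kinds: Tuple[str, ...] = ("sphere", "ellipsoid"),
    rendered: bool = False,
) -> PhantomConfig:
    """Draw one random phantom from the study family.

    Tumors are 7-12 mm spheres or 6-12 mm semi-axis ellipsoids (optionally
    lobulated); trajectories are raised-cosine loops of 2-20 mm peak-to-peak
    amplitude along a random SI-dominant 3D direction with 0-4 mm hysteresis.
    With ``rendered=False`` the config renders noiseless, unblurred phases
    (only the geometry is exercised).
    """
    kind = str(rng.choice(list(kinds)))
    radius = float(rng.uniform(7, 12))
    semi = tuple(float(s) for s in np.sort(rng.uniform(6, 12, 3))[::-1])
    amp = float(amplitude_mm) if amplitude_mm is not None else float(rng.uniform(2, 20))
    hyst = float(rng.uniform(0, 4))
    v = np.array(
        [rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), rng.choice([-1.0, 1.0])]
    )
    v /= np.linalg.norm(v)
    w = np.cross(v, [1.0, 0.0, 0.0])
    w /= np.linalg.norm(w)
    theta = 2.0 * np.pi * np.arange(10) / 10.0
    d = np.outer(amp / 2.0 * (1.0 + np.cos(theta)), v) + np.outer(
        hyst / 2.0 * np.sin(theta), w
    )
    d -= d[PHASE_LABELS.index(DEFAULT_REFERENCE)]
    return PhantomConfig(
        shape_kind=kind,
        radius_mm=radius,
        semi_axes_mm=semi,
        lobulation_amplitude=float(rng.uniform(0.15, 0.3))
        if kind == "lobulated"
        else 0.25,
        trajectory=d,
        noise_sd_hu=20.0 if rendered else 0.0,
        blur_sigma_mm=1.2 if rendered else 0.0,
        chest_wall=rendered,
        seed=int(rng.integers(2**31)),
    )


def analytic_igtv(config: PhantomConfig, step_mm: float = 0.5) -> BinaryMask:
    """The phantom's exact motion-envelope iGTV as a mask on its grid."""
    return BinaryMask(config.grid, _analytic_envelope(config, step_mm))


# ---------------------------------------------------------------------------
# Observer-variation perturbations
# ---------------------------------------------------------------------------


def perturb_igtv(
    igtv: BinaryMask, mode: str, magnitude_mm: float, seed: int = 0
) -> BinaryMask:
    """Controlled corruption of an iGTV emulating observer variation.

    Modes:

    * ``dilate`` / ``erode`` — isotropic margin error of ``magnitude_mm``;
    * ``drop_superior`` — the superior ``magnitude_mm`` of the envelope is
      missing (under-contoured motion extent);
    * ``notch`` — a spherical bite of radius ``magnitude_mm`` taken out of
      the surface at a seeded random location (local shape inconsistency,
      the kind the iGTV volume-ratio QA is designed to flag).
    """
    if magnitude_mm < 0:
        raise ParameterError("perturbation magnitude must be non-negative")
    if magnitude_mm == 0:
        return BinaryMask(igtv.geometry, igtv.voxels.copy())
    g = igtv.geometry
    if mode == "dilate":
        out = ndimage.binary_dilation(
            igtv.voxels, structure=ball_footprint(g, magnitude_mm)
        )
    elif mode == "erode":
        out = ndimage.binary_erosion(
            igtv.voxels, structure=ball_footprint(g, magnitude_mm)
        )
    elif mode == "drop_superior":
        out = igtv.voxels.copy()
        ks = np.flatnonzero(out.any(axis=(0, 1)))
        z_top = g.axis_coords(2)[ks[-1]]
        cut = g.axis_coords(2) > z_top - magnitude_mm
        out[:, :, cut] = False
    elif mode == "notch":
        rng = np.random.default_rng(seed)
        boundary = igtv.voxels & ~ndimage.binary_erosion(igtv.voxels)
        idx = np.argwhere(boundary)
        center = g.index_to_mm(idx[rng.integers(len(idx))])
        x, y, z = _voxel_centers(g)
        ball = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (
            z - center[2]
        ) ** 2 <= magnitude_mm**2
        out = igtv.voxels & ~ball
    else:
        raise ParameterError(f"unknown perturbation mode {mode!r}")
    if not out.any():
        raise DegenerateMaskError(f"perturbation {mode!r} emptied the mask")
    return BinaryMask(g, out)
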