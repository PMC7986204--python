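"""Volumes, masks and contours on a common grid contract.

Coordinate convention used throughout the package:

* arrays are indexed ``[i, j, k]`` along the (LR, AP, SI) patient axes;
* voxel indices are 0-based; a voxel's position is its **centre** in mm,
  ``mm = origin + index * spacing`` (an affine bijection per axis);
* spacings are mm per axis, strictly positive; all translations are in mm.

Volumes and masks are stored as NIfTI (via nibabel, diagonal affine).
Contours use a small JSON dialect::

    {"slices": [{"z_mm": <float>, "polygons": [[[x_mm, y_mm], ...], ...]}]}

Polygons are closed implicitly (last vertex joins the first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import nibabel as nib
import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

from .exceptions import (
    ContourPlacementError,
    EmptyMaskError,
    FormatError,
    GridMismatchError,
    ParameterError,
    ShapeError,
)

AXIS_LABELS: Tuple[str, str, str] = ("LR", "AP", "SI")

#: The ten respiratory bins of a 4D-CT series, in percent of the cycle.
PHASE_LABELS: Tuple[int, ...] = tuple(range(0, 100, 10))

#: Reference phase: 50% (near peak exhalation, the most stable position).
DEFAULT_REFERENCE: int = 50


@dataclass(frozen=True)
class GridGeometry:
    """A regular 3D grid: voxel counts, spacing (mm) and origin (mm).

    ``origin`` is the mm position of the centre of voxel (0, 0, 0).
    Default spacing follows routine lung 4D-CT reconstruction
    (1.17 mm square pixels, 3 mm slices).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (1.17, 1.17, 3.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ShapeError("GridGeometry is strictly three-dimensional")
        if any(n <= 0 for n in self.shape):
            raise ParameterError(f"non-positive voxel counts: {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"non-positive spacing: {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- affine index <-> mm mapping -------------------------------------
    def index_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices (may be fractional) to mm positions."""
        return np.asarray(index, dtype=float) * np.array(self.spacing) + np.array(
            self.origin
        )

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        """Map (…, 3) mm positions to fractional voxel indices."""
        return (np.asarray(mm, dtype=float) - np.array(self.origin)) / np.array(
            self.spacing
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """mm positions of all voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape: Sequence[int], affine: np.ndarray) -> "GridGeometry":
        rot = np.asarray(affine)[:3, :3]
        spacing = tuple(float(s) for s in np.sqrt((rot**2).sum(axis=0)))
        origin = tuple(float(o) for o in np.asarray(affine)[:3, 3])
        return cls(tuple(int(n) for n in shape), spacing, origin)


@dataclass
class ImageVolume:
    """One respiratory phase: a 3D scalar HU grid with its geometry."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ShapeError(f"expected 3D intensities, got {self.values.ndim}D")
        if tuple(self.values.shape) != self.geometry.shape:
            raise GridMismatchError(
                f"array shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("intensities must be finite")


@dataclass
class BinaryMask:
    """A boolean grid on a stated geometry (tumor, iGTV, VOI, ...)."""

    geometry: GridGeometry
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ShapeError(f"expected 3D mask, got {self.voxels.ndim}D")
        if tuple(self.voxels.shape) != self.geometry.shape:
            raise GridMismatchError(
                f"mask shape {self.voxels.shape} != geometry {self.geometry.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_cc(self) -> float:
        # count * voxel volume: reproducible bit-exactly for a given mask
        return self.count * self.geometry.voxel_volume_cc

    def centroid_mm(self) -> np.ndarray:
        """Unweighted centre of mass of the true voxels, in mm."""
        if self.is_empty:
            raise EmptyMaskError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.voxels)
        return self.geometry.index_to_mm(idx.mean(axis=0))


@dataclass
class PhaseSeries:
    """Ten phase volumes (0%..90%) sharing one grid, with a reference phase."""

    phases: Dict[int, ImageVolume]
    reference_label: int = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        if tuple(sorted(self.phases)) != PHASE_LABELS:
            raise ParameterError(
                f"a 4D-CT series has exactly the phases {PHASE_LABELS}"
            )
        geoms = {vol.geometry for vol in self.phases.values()}
        if len(geoms) != 1:
            raise GridMismatchError("all phases must share one GridGeometry")
        if self.reference_label not in self.phases:
            raise ParameterError(f"reference phase {self.reference_label} missing")

    @property
    def geometry(self) -> GridGeometry:
        return self.phases[self.reference_label].geometry

    @property
    def reference(self) -> ImageVolume:
        return self.phases[self.reference_label]


@dataclass
class ContourSlice:
    z_mm: float
    polygons: List[np.ndarray] = field(default_factory=list)


@dataclass
class ContourSet:
    """Per-slice closed planar polygons, vertices in mm (x=LR, y=AP)."""

    slices: List[ContourSlice] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Volume / mask / contour I/O
# ---------------------------------------------------------------------------


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI volume; HU values and header geometry are preserved."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ShapeError(f"{path!r}: expected a 3D payload, got {data.ndim}D")
    geometry = GridGeometry.from_affine(data.shape, img.affine)
    return ImageVolume(geometry, np.asarray(data, dtype=np.float32))


def write_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.values, dtype=np.float32), volume.geometry.affine
    )
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.geometry, vol.values > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.geometry.affine)
    nib.save(img, str(path))


def read_contours(path) -> ContourSet:
    try:
        payload = json.loads(Path(path).read_text())
        slices = [
            ContourSlice(
                z_mm=float(entry["z_mm"]),
                polygons=[np.asarray(p, dtype=float) for p in entry["polygons"]],
            )
            for entry in payload["slices"]
        ]
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read contours {path!r}: {exc}") from exc
    for sl in slices:
        for poly in sl.polygons:
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise FormatError("polygons must be (N, 2) [x_mm, y_mm] arrays")
    return ContourSet(slices)


def write_contours(contours: ContourSet, path) -> None:
    payload = {
        "slices": [
            {
                "z_mm": round(float(sl.z_mm), 6),
                "polygons": [
                    [[round(float(x), 6), round(float(y), 6)] for x, y in poly]
                    for poly in sl.polygons
                ],
            }
            for sl in contours.slices
        ]
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# Contour <-> mask conversion
# ---------------------------------------------------------------------------


def rasterize_contours(contours: ContourSet, geometry: GridGeometry) -> BinaryMask:
    """Voxel-centre even-odd rasterisation of planar contours.

    A voxel is true iff its centre lies inside an odd number of that slice's
    polygons. Contour z positions must coincide with slice planes to within
    half a slice thickness.
    """
    nx, ny, nz = geometry.shape
    out = np.zeros(geometry.shape, dtype=bool)
    xs = geometry.axis_coords(0)
    ys = geometry.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    oz, sz = geometry.origin[2], geometry.spacing[2]
    for sl in contours.slices:
        k = int(round((sl.z_mm - oz) / sz))
        if k < 0 or k >= nz or abs(sl.z_mm - (oz + k * sz)) > sz / 2 + 1e-9:
            raise ContourPlacementError(
                f"contour slice z={sl.z_mm} mm is off the grid's slice planes"
            )
        inside = np.zeros(nx * ny, dtype=bool)
        for poly in sl.polygons:
            if len(poly) < 3:
                continue
            # contains_points closes the polygon implicitly
            inside ^= MplPath(poly).contains_points(points)
        out[:, :, k] ^= inside.reshape(nx, ny)
    return BinaryMask(geometry, out)


def extract_contours(mask: BinaryMask) -> ContourSet:
    """Trace per-slice closed boundary polygons at iso-level 0.5.

    Symmetric with :func:`rasterize_contours`: re-rasterising the result
    reproduces the mask.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot extract contours from an empty mask")
    geometry = mask.geometry
    slices: List[ContourSlice] = []
    for k in range(geometry.shape[2]):
        plane = mask.voxels[:, :, k]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        polygons = []
        for contour in measure.find_contours(padded, 0.5):
            verts_idx = contour - 1.0  # undo padding; (x_idx, y_idx) columns
            xy = np.column_stack(
                [
                    geometry.origin[0] + verts_idx[:, 0] * geometry.spacing[0],
                    geometry.origin[1] + verts_idx[:, 1] * geometry.spacing[1],
                ]
            )
            # find_contours closes loops on padded binary input: drop the
            # duplicated last vertex, polygons close implicitly
            if np.allclose(xy[0], xy[-1]):
                xy = xy[:-1]
            polygons.append(xy)
        z = geometry.origin[2] + k * geometry.spacing[2]
        slices.append(ContourSlice(z_mm=z, polygons=polygons))
    return ContourSet(slices)


# ---------------------------------------------------------------------------
# SI resampling (3 mm -> 1 mm working grid)
# ---------------------------------------------------------------------------


def resample_mask_si(mask: BinaryMask, new_slice_mm: float = 1.0) -> BinaryMask:
    """Resample a mask along SI by nearest-neighbour to a new slice thickness.

    The physical extent (slice slabs, not centres) is preserved; in-plane
    geometry is untouched. Resampling to the current thickness is an identity.
    """
    if new_slice_mm <= 0:
        raise ParameterError("slice thickness must be positive")
    geometry = mask.geometry
    sz = geometry.spacing[2]
    if abs(new_slice_mm - sz) < 1e-12:
        return BinaryMask(geometry, mask.voxels.copy())
    nz = geometry.shape[2]
    extent = nz * sz  # from first slab's lower face to last slab's upper face
    start = geometry.origin[2] - sz / 2.0
    n_new = max(1, int(round(extent / new_slice_mm)))
    new_centers = start + new_slice_mm * (np.arange(n_new) + 0.5)
    src = np.clip(
        np.round((new_centers - geometry.origin[2]) / sz).astype(int), 0, nz - 1
    )
    new_geom = GridGeometry(
        (geometry.shape[0], geometry.shape[1], n_new),
        (geometry.spacing[0], geometry.spacing[1], float(new_slice_mm)),
        (geometry.origin[0], geometry.origin[1], float(new_centers[0])),
    )
    return BinaryMask(new_geom, mask.voxels[:, :, src])
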