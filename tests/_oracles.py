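"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive (loops, closed forms, exhaustive
point tests) and shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

from gtvgen.imaging_io import BinaryMask, GridGeometry
from gtvgen.phantom import PhantomConfig


# ---------------------------------------------------------------------------
# Planar geometry
# ---------------------------------------------------------------------------


def brute_point_in_polygon(px: float, py: float, poly: np.ndarray) -> bool:
    """Ray-casting even-odd test for one point against one closed polygon."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
            if px < x_cross:
                inside = not inside
    return inside


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------


def brute_correlation_ratio(
    fixed: np.ndarray, moving: np.ndarray, n_bins: int = 32, min_count: int = 5
) -> float:
    """Per-bin conditional-variance eta^2, written as explicit loops."""
    fixed = np.asarray(fixed, float).ravel()
    moving = np.asarray(moving, float).ravel()
    lo, hi = fixed.min(), fixed.max()
    width = (hi - lo) / n_bins
    groups = []
    for b in range(n_bins):
        if b < n_bins - 1:
            sel = (fixed >= lo + b * width) & (fixed < lo + (b + 1) * width)
        else:
            sel = (fixed >= lo + b * width) & (fixed <= hi)
        if sel.sum() >= min_count:
            groups.append(moving[sel])
    pooled = np.concatenate(groups)
    total = pooled.var()
    within = sum(g.var() * g.size for g in groups) / pooled.size
    return float(np.clip(1.0 - within / total, 0.0, 1.0))


def brute_surface_points(mask: BinaryMask) -> np.ndarray:
    """Boundary voxel centres by explicit 6-neighbour inspection."""
    v = mask.voxels
    padded = np.pad(v, 1)
    pts = []
    for i, j, k in np.argwhere(v):
        ii, jj, kk = i + 1, j + 1, k + 1
        if not (
            padded[ii - 1, jj, kk]
            and padded[ii + 1, jj, kk]
            and padded[ii, jj - 1, kk]
            and padded[ii, jj + 1, kk]
            and padded[ii, jj, kk - 1]
            and padded[ii, jj, kk + 1]
        ):
            pts.append((i, j, k))
    return mask.geometry.index_to_mm(np.array(pts))


def brute_dta(test: BinaryMask, reference: BinaryMask) -> tuple:
    """All-pairs directed nearest-surface distances (mean, SD)."""
    pt = brute_surface_points(test)
    pr = brute_surface_points(reference)
    dists = np.sqrt(((pt[:, None, :] - pr[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    return float(dists.mean()), float(dists.std())


def brute_centroid(mask: BinaryMask) -> np.ndarray:
    acc = np.zeros(3)
    n = 0
    for idx in np.argwhere(mask.voxels):
        acc += mask.geometry.index_to_mm(idx)
        n += 1
    return acc / n


def brute_amplitude(offsets: np.ndarray) -> float:
    rngs = [offsets[:, a].max() - offsets[:, a].min() for a in range(3)]
    return float(np.sqrt(sum(r * r for r in rngs)))


# ---------------------------------------------------------------------------
# Continuous-space envelope-intersection oracle
# ---------------------------------------------------------------------------


def _shape_scale(config: PhantomConfig) -> np.ndarray:
    """Per-axis scaling that maps the convex tumor onto the unit ball."""
    if config.shape_kind == "sphere":
        return np.full(3, 1.0 / config.radius_mm)
    if config.shape_kind == "ellipsoid":
        return 1.0 / np.asarray(config.semi_axes_mm, float)
    raise ValueError("the continuous oracle handles convex shapes only")


def oracle_generate(
    config: PhantomConfig, forward: np.ndarray, work_geom: GridGeometry
) -> BinaryMask:
    """Intersect analytic motion envelopes at float precision, voxelise last.

    The envelope is all points within unit scaled distance of the forward
    polyline; the intersection is taken over the ten reverse-shifted copies,
    evaluated exactly at every working-grid voxel centre.
    """
    W = _shape_scale(config)
    x = work_geom.axis_coords(0)[:, None, None]
    y = work_geom.axis_coords(1)[None, :, None]
    z = work_geom.axis_coords(2)[None, None, :]
    c = config.center
    segs = list(zip(forward[:-1], forward[1:]))
    reverse = -forward
    out = np.ones(work_geom.shape, dtype=bool)
    for k in range(10):
        qx = (x - reverse[k][0] - c[0]) * W[0]
        qy = (y - reverse[k][1] - c[1]) * W[1]
        qz = (z - reverse[k][2] - c[2]) * W[2]
        mind = np.full(work_geom.shape, np.inf)
        for a, b in segs:
            aw, bw = a * W, b * W
            ab = bw - aw
            denom = float((ab**2).sum())
            px, py, pz = qx - aw[0], qy - aw[1], qz - aw[2]
            if denom < 1e-12:
                dd = px**2 + py**2 + pz**2
            else:
                t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / denom, 0.0, 1.0)
                dd = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
            np.minimum(mind, dd, out=mind)
        out &= mind <= 1.0
    return BinaryMask(work_geom, out)


def oracle_envelope(
    config: PhantomConfig, forward: np.ndarray, geom: GridGeometry
) -> BinaryMask:
    """Voxelisation of the exact analytic envelope (single copy, no shifts)."""
    W = _shape_scale(config)
    x = geom.axis_coords(0)[:, None, None]
    y = geom.axis_coords(1)[None, :, None]
    z = geom.axis_coords(2)[None, None, :]
    c = config.center
    mind = np.full(geom.shape, np.inf)
    for a, b in zip(forward[:-1], forward[1:]):
        aw, bw = a * W, b * W
        ab = bw - aw
        denom = float((ab**2).sum())
        px = (x - c[0]) * W[0] - aw[0]
        py = (y - c[1]) * W[1] - aw[1]
        pz = (z - c[2]) * W[2] - aw[2]
        if denom < 1e-12:
            dd = px**2 + py**2 + pz**2
        else:
            t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / denom, 0.0, 1.0)
            dd = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
        np.minimum(mind, dd, out=mind)
    return BinaryMask(geom, mind <= 1.0)
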