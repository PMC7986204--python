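"""Swept-volume removal: generate a GTV from an iGTV and a motion path.

The iGTV is the tumor's motion envelope — the reference tumor plus the
volume it sweeps over the breathing cycle. Shifting the envelope along the
*reverse* motion path keeps the reference tumor inside every shifted copy,
so the tumor is contained in (and for convex shapes equals) the intersection
of all shifted envelopes. Working on a 1 mm-SI resampled grid lets small SI
translation components act at sub-slice resolution, as routine 3 mm slices
would otherwise quantise them away.
"""

from __future__ import annotations

import numpy as np

from .exceptions import (
    DegenerateMaskError,
    EmptyMaskError,
    GenerationFailure,
    ParameterError,
)
from .imaging_io import BinaryMask, resample_mask_si
from .phantom import _integer_shift, build_envelope_union
from .registration import MotionPath, Translation

#: SI slice thickness of the working grid (mm).
WORKING_SI_MM: float = 1.0


def shift_mask(mask: BinaryMask, t: Translation) -> BinaryMask:
    """Translate a mask by ``t`` mm via per-axis nearest-neighbour sampling.

    Equivalent to rounding each component of ``t`` to whole voxels of the
    mask's grid; voxels shifted outside the grid are dropped.
    """
    if not isinstance(t, Translation):
        t = Translation.from_array(t)
    steps = np.round(t.as_array() / np.array(mask.geometry.spacing)).astype(int)
    out = _integer_shift(mask.voxels, steps)
    if not out.any() and not mask.is_empty:
        raise DegenerateMaskError("shift moved the entire mask off-grid")
    return BinaryMask(mask.geometry, out)


def generate_gtv(
    igtv: BinaryMask, path: MotionPath, working_si_mm: float = WORKING_SI_MM
) -> BinaryMask:
    """Intersect the iGTV shifted along the reverse motion path.

    ``path`` holds the translations mapping each phase's tumor onto the
    reference (the registration output). The iGTV is resampled to the 1 mm
    working grid, shifted by each of the nine non-reference translations, and
    the voxelwise AND of all ten masks is returned.

    Raises :class:`GenerationFailure` on an empty intersection (complete
    generation failure, no contour produced).
    """
    if igtv.is_empty:
        raise EmptyMaskError("cannot generate a GTV from an empty iGTV")
    work = resample_mask_si(igtv, working_si_mm)
    acc = work.voxels.copy()
    for label, t in path.shifts.items():
        if label == path.reference_label:
            continue
        steps = np.round(
            t.as_array() / np.array(work.geometry.spacing)
        ).astype(int)
        acc &= _integer_shift(work.voxels, steps)
    if not acc.any():
        raise GenerationFailure("empty envelope intersection: no contour produced")
    return BinaryMask(work.geometry, acc)


def reconstruct_igtv(
    gtv: BinaryMask, path: MotionPath, step_mm: float = 0.5
) -> BinaryMask:
    """Union of the generated GTV along the densified forward trajectory.

    Reverses the generation process: ``path`` is the same reverse motion path
    used for generation; its negation is the forward trajectory. Used for
    the iGTV volume-ratio quality check — the reconstructed envelope can
    never exceed the observed iGTV that produced the GTV, and falls short of
    it exactly where the observed contour is inconsistent with the motion.
    """
    if gtv.is_empty:
        raise EmptyMaskError("cannot reconstruct an envelope from an empty GTV")
    return build_envelope_union(gtv, path.negated(), step_mm)


def igtv_volume_ratio(igtv_gen: BinaryMask, igtv_obs: BinaryMask) -> float:
    """vol(iGTV_gen) / vol(iGTV_obs); close to one for a consistent iGTV.

    The observed iGTV is resampled to the generated mask's SI spacing when
    the two grids differ, so both volumes are measured on the working grid.
    """
    if igtv_gen.is_empty or igtv_obs.is_empty:
        raise EmptyMaskError("volume ratio of an empty mask is undefined")
    obs = igtv_obs
    if obs.geometry != igtv_gen.geometry:
        obs = resample_mask_si(obs, igtv_gen.geometry.spacing[2])
    if obs.volume_cc == 0:
        raise ParameterError("observed iGTV has zero volume")
    return igtv_gen.volume_cc / obs.volume_cc
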