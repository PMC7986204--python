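# Methods

## The problem and the model

Patients with early-stage lung cancer planned for stereotactic ablative
radiotherapy (SABR) receive a 4D-CT: ten 3D volumes binned over the breathing
cycle (0% = inhale peak). Clinically, the tumor is often delineated only as an
**iGTV** — the union of the tumor over all phases, i.e. its motion envelope —
so the tumor itself (the **GTV**) is never contoured and is unavailable for
retrospective volume, prognostic and radiomics analyses.

gtvgen recovers the GTV from the iGTV and the phase images. The model treats
the tumor as a rigid body translating along a piecewise-linear trajectory
through its ten phase positions; rotation and deformation are assumed small
relative to translation. Writing V\*ref for the tumor at the reference phase
and Venv for its motion envelope,

* the envelope decomposes as Venv = V\*ref ∪ V\*SW (reference plus swept
  volume);
* shifting the envelope so the reference tumor occupies each phase position
  keeps V\*ref inside every shifted copy, so
  V\*ref ⊆ ⋂ₖ Venv(tₖ) — the intersection over the reverse motion path;
* for convex tumors the inclusion is an equality, so the intersection *is*
  the tumor; for non-convex tumors it is a tight superset.

The pipeline therefore: (1) estimates the translation mapping each phase's
tumor onto the 50% reference phase (near peak exhalation, the most stable
position) by local rigid registration; (2) resamples the iGTV mask to a 1 mm
SI working grid; (3) translates it by each of the nine estimated shifts and
intersects all ten masks; (4) extracts the result as the generated GTV.

## Registration

Translation-only, restricted to a VOI around the iGTV, maximising the
**correlation ratio** η² = 1 − E[Var(moving | fixed bin)]/Var(moving) over the
VOI. Four VOI strategies are run per case: (1) iGTV + 4 mm spherical margin;
(2) the same minus the morphologically closed >176 HU (bone/cartilage) set;
(3) the same with a prior SI translation following 2 cm peak-to-peak
breathing as initialisation; (4) a 10 mm total margin for mobile,
low-contrast tumors. Phases are visited cyclically from the reference
(60%…90%, 0%…40%), each registration prematched with the previous result.
The strategy whose nine costs have the smallest SD is selected, on the
rationale that the most successful registration produces the most consistent
cost.

Numerical choices:

* **Optimizer** — deterministic coarse-to-fine grid search: a 2 mm grid over
  ±8 mm around the initialisation, then refinement at 1, 0.5 and 0.25 mm
  (±2 steps each) around the incumbent, capped at a 25 mm total search
  radius. Reproducible and derivative-free; adequate because prematching
  keeps the true optimum within a few mm of the initialisation.
* **Cost binning** — 32 equal-width bins of the fixed image over the masked
  HU range; bins with fewer than 5 voxels are dropped. With finite bins,
  exact functional dependence scores slightly below 1 (within-bin residual
  variance); identity registrations on the phantom score ≈ 0.98.
* **Interpolation** — trilinear for the moving image during registration
  (sub-voxel cost smoothness); masks are always shifted by nearest-neighbour
  (per-axis rounding to the grid).
* **Cost SD** — sample SD (ddof = 1) over the nine phase costs.

## Generation, reconstruction and QA

The working grid keeps the in-plane spacing and resamples SI to 1 mm by
nearest-neighbour, so small SI shifts act at sub-slice resolution; in-plane
sub-pixel residues (< 0.59 mm for 1.17 mm pixels) are accepted. The
intersection is taken at the ten phase stations; an empty intersection raises
a generation-failure signal rather than returning an empty mask.

Quality assurance reverses the process: the generated GTV is swept along the
densified (0.5 mm steps) forward trajectory and the **iGTV volume ratio**
vol(iGTV_gen)/vol(iGTV_obs) is computed. The reconstructed envelope can never
exceed the observed iGTV that produced the GTV; it falls short exactly where
the observed contour is inconsistent with the estimated motion. Gates, with
their published operating points as configurable defaults: registration
fails if mean cost < 0.73 or cost SD ≥ 0.13; a generated contour is routed
to visual "check" if the ratio < 0.84, and trusted otherwise. Ratios
slightly above 1 (≤ ~1.06) arise from interpolation when the observed iGTV
is compared on the working grid and are not a concern. Human visual ratings
are represented only as an optional manual-override field.

An important property of the ratio, documented here because tests probe it:
**corruptions that commute with envelope formation are invisible to it.**
A uniform dilation or erosion of a swept sphere is itself an exact envelope
(of a larger/smaller tumor), and a planar truncation of an SI-swept envelope
is the envelope of the correspondingly cut tumor — in all these cases the
ratio stays ≈ 1 however large the margin error. The ratio responds to
*shape inconsistency* between contour and motion: local bites/notches,
envelope extents incompatible with the trajectory direction, or registration
error. The phantom's `notch` perturbation exists to exercise exactly this
mechanism.

## Validation metrics

Directed surface distance-to-agreement (DTA): for every surface point of the
generated contour, the Euclidean distance to the nearest surface point of
the reference, with mean and SD across the surface (deliberately *not* the
median-surface SD used in observer-variability studies). Surface points are
the centres of 6-connectivity boundary voxels on the working grid, making
DTA values reproducible bit-exactly. Volume ratio is generated/reference.
Centre-of-mass distance uses unweighted true-voxel centroids (the intensity
weighting of the original is unstated; unweighted is the simpler convention
and is documented here).

## The phantom

The generator emulates routine lung 4D-CT at reduced field of view: a
96×96×40 grid at 1.17×1.17×3 mm (the clinical reconstruction conventions),
lung parenchyma at −800 HU, tumor at +20 HU, an optional chest-wall slab at
+300 HU (straddling the 176 HU bone threshold so chest-wall removal is
exercisable), Gaussian PSF blur of σ = 1.2 mm and Gaussian noise of SD
20 HU. Tumors are spheres, ellipsoids or lobulated spheres (smooth radial
bumps); the default 10 mm radius gives a ~4.2 cc GTV, typical of SABR
lesions. The default trajectory is a raised-cosine SI waveform,
d_SI(k) = A/2·(1 + cos(2πk/10)) — maximal at the 0% inhale peak, zero at the
50% reference — with default peak-to-peak A = 10 mm (clinical cohort means
sit near 7 mm) and an elliptical AP hysteresis loop of width 2 mm (typical
reported hysteresis is 1–5 mm). The displacement direction is configurable;
the geometry is reflection-symmetric, so the sign convention carries no
physical consequence. The randomized study family draws 7–12 mm tumors,
2–20 mm amplitudes along random SI-dominant 3D directions and 0–4 mm
hysteresis loops.

The ground-truth iGTV is voxelised analytically (a voxel is true iff its
centre lies inside the continuously swept tumor, trajectory densified at
0.5 mm), emulating an observer contouring the envelope slice by slice.
Observer variation is emulated by controlled perturbations: isotropic
dilation/erosion, superior truncation, and local spherical notches.

What the phantom does **not** model: tumor deformation or rotation, 4D-CT
binning/stitching artifacts, attachment to vessels or chest wall,
low-contrast ground-glass extensions, and irregular breathing. Passing tests
therefore demonstrate the geometric and numerical correctness of the method
under its own rigid-body assumptions, not clinical performance.

## Discretisation behaviour and known limitations

* The mask-based station intersection carries a small *inward* bias: each of
  the nine shifts is rounded per axis to the working grid (≤ 0.59 mm
  in-plane, ≤ 0.5 mm SI), and the intersection takes the minimum over all
  copies, so rounding residues accumulate one-sidedly. Together with the
  3 mm slice quantisation of the input contour this underestimates the
  convex-tumor volume by typically 3–10% (worst ~14%) relative to a
  continuous-space oracle on the randomized family, with surface deviations
  up to about two working voxels locally; centre-of-mass error stays well
  under 0.5 mm. This mirrors the predominance of volume underestimation
  reported for the clinical method and is inherent to nearest-neighbour
  mask arithmetic, not a tunable defect.
* The iGTV volume ratio is blind to commuting corruptions (see above): it is
  a consistency check, not a margin-error detector.
* Single lesions only; no deformable registration; thresholds are operating
  points chosen for a specific clinical cohort and should be re-derived for
  other scanners/protocols.

## Problem sizes used in the shipped tests and script

The test suite and `scripts/acceptance.py` run phantoms on the default
96×96×40 grid (1 mm working grid: 96×96×120): 20 randomized convex phantoms
for oracle recovery, 50 for the nesting property, 25 perturbation runs for
ratio behaviour, and full four-method registrations on two noisy phantoms —
sizes chosen so a complete run takes a few minutes on one CPU while keeping
every geometric regime (small/large amplitude, convex/lobulated) covered.
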