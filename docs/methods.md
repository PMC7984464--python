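# Methods

This note documents the models, defaults, and numerical choices behind
`parotidspare`, and what the synthetic study conditions do and do not
show about clinical data.

## Coordinate and grid conventions

Patient millimetre coordinates, head-first supine, axis-aligned grids
only (+x patient left, +y posterior, +z superior); oblique orientations
are rejected with an explicit error. Dose arrays are indexed
`values[iz, iy, ix]`; origins and spacings refer to voxel centers.
Structures are rasterized onto the dose grid (never the reverse), so
every metric is evaluated on a single grid without double interpolation.
Rasterization tests voxel centers against the contour polygon of the
nearest slice (within half a slice spacing) by the even-odd rule; there
is no partial-volume weighting, which is below the precision of
everything downstream. RT-DOSE files are written as 32-bit unsigned
integers with a per-file scaling that maps the grid maximum to the full
integer range, bounding round-trip error by `max(dose) / 2^32`.

## Equal-volume subsegmentation

The gland mask is split into 18 cells by nested voxel-count quantiles:
cranio-caudal into 3 equal-count slabs, each slab antero-posterior into
3, each cell medial-lateral into 2. Quantile boundaries use rounded
cumulative fractions of the sorted voxel list (sort key: split axis,
then the remaining axes in (z, y, x) order; boundary voxels go to the
lower cell), so each cell deviates from N/18 by at most ~2 voxels —
within the 2% tolerance the package guarantees for glands of ≥ ~2,000
voxels. The nesting order (cranio-caudal, antero-posterior,
medial-lateral) is a package choice; published equal-volume
subsegmentations do not fully specify it, and the octant-to-rank
assignment is therefore configuration, not code.

Cells are relabeled S1→S18 by decreasing relative importance via the
octant map. The medial-lateral axis is interpreted per laterality
(mirrored for left glands) so anatomical ranks agree between sides.
**The shipped importance table is a placeholder**: only two facts about
it are population-derived — the most important subsegment is
caudal-anterior with 3.85x the homogeneous-gland expectation, and the
least important subsegment carries virtually none. The default fills the
remaining ranks with a geometric decay (ratio 0.8, normalized to
I1 = 1) laid out caudal→cranial, anterior→posterior, medial→lateral.
Replace `data/importance_18.json` with published per-subsegment values
for any clinical interpretation.

## Artificial base plans and constraint bookkeeping

A base-plan variant assigns, per voxel: 0 outside the CPG; 0 in CPG∩PTV
(union over PTV-like structures), so target coverage is never traded
away; otherwise a dose uniform within each subsegment — `D0 * I_k` in
proportional mode (`BP_10/20/30`, and `BP_20,5` restricted to S1–S5) or
a flat 50 Gy on S1–S5 (`BP_top5`). The accompanying constraints for an
optimizer that absorbs the base plan are:

- CPG Dmax bound = max(BP) + margin, margin a required user parameter in
  [0, 15] Gy (the appropriate value depends on the individual anatomy);
- CPG whole-mean bound = clinical bound + mean(BP | CPG), because the
  base plan's in-gland mean is absorbed into the gland mean during
  optimization.

Both identities are exact and tested to machine precision; proportional
variants with equal margins have Dmax bounds that differ by exactly
their D0 differences.

## Hill-ensemble outcome model

Predicted stimulated saliva output at 1 year relative to baseline:

    S(D_1..D_18) = 1 − Σ_i Δ_i · [1 − 1 / (1 + (D_i / D50_i)^(n_i))]

with Δ_i ≥ 0, Σ Δ_i ≤ 1, D50_i > 0, n_i > 0. S is 1 at zero dose,
non-increasing in every D_i, and bounded below by 1 − ΣΔ. Per-subsegment
curves are fit by bounded least squares (Δ ∈ [0,1], D50 ∈ (0,200] Gy,
n ∈ (0,20]) to responses sampled on a 0:2:40 Gy ladder, with the
baseline r(0) taken from the zero-dose point (the other subsegments hold
a constant, not necessarily zero, dose). Fitting is deterministic:
8 starts over a log-spaced D50 grid in [2, 100] Gy, best cost wins;
fits with Δ ≤ 1e-3 are flagged unidentifiable in D50/n. Noiseless fits
recover generating parameters within 1%; with response noise of
σ = 0.01, the median of 100 replicate Δ estimates stays within 5% of
truth (both are regression-tested).

**The shipped Hill parameters are synthetic** (`data/hill_18.json`):
Δ_i proportional to the placeholder importance values with ΣΔ = 0.9,
D50 rising from 20 to 28.5 Gy with rank, n = 2 throughout. They preserve
the structure of the ensemble — not clinical values — because the
population model the published parameters came from is not
redistributable. All identity tests (half-Δ decline at D50, saturation,
monotonicity) are parameter-independent.

Reported improvements are rounded half-up to integer percent, the
precision at which such comparisons are conventionally reported
(e.g. 0.54 vs 0.48 → 13% relative, 6 points absolute).

## Synthetic phantoms

`PhantomConfig` defaults encode the cohort-scale facts the package is
demonstrated on: an ellipsoidal CPG with semiaxes (16, 19, 25) mm
(31.8 cc) on the patient's right, a spherical 181.5 cc PTV placed
medially-caudally by bisection to hit a requested CPG overlap fraction
(default 13%, tolerance ±0.02; a zero-overlap request places the PTV at
a 33 mm surface gap), 70 Gy prescription, 2.5 mm isotropic grid. Dose is
the prescription inside the PTV with `exp(−d/12 mm)` falloff outside —
a realistic gradient across the gland without a beam model — plus
optional zero-truncated Gaussian noise (off by default so the monotone
falloff invariant holds exactly). Cohorts jitter each semiaxis by ±20%
and sample the overlap fraction uniformly in [0, 0.33]; everything is
deterministic under a seed.

What the phantoms do **not** emulate: real gland shapes (no lobes, no
duct geometry), secondary/elective target volumes, other organs at
risk, CT heterogeneity, or setup uncertainty. Tests passing on phantoms
validate the method's arithmetic and mechanism, not clinical effect
sizes.

## Demonstration optimizer

`demo_opt` is explicitly a demonstration, not a VMAT emulator: pencil
beamlets on a (gantry angle x lateral x longitudinal) grid with
exponential depth attenuation (0.005/mm) and a Gaussian transverse
profile (σ = width/2, cut at 2.5σ), a convex objective of one-sided
quadratic penalties, and L-BFGS-B over non-negative beamlet weights with
deterministic initialization and a fixed iteration budget (default
300; the convex objective plus monotone line search makes accepted
iterates non-increasing). Objective weights are normalized by their sum,
so scaling all weights leaves the optimum exactly unchanged.

Three modelling choices matter and are deliberate:

- CPG penalty terms are evaluated on (optimized + base-plan) dose,
  mirroring how a planning system absorbs a base plan; the returned dose
  excludes the base plan, which is artificial and never delivered.
- The Dmax penalty acts on CPG∖PTV. The base plan zeroes CPG∩PTV
  precisely so that coverage is unaffected; letting the bound fight the
  prescription inside the overlap would contradict that intent.
- A small always-active quadratic pressure on the physical CPG mean
  (weight 20 vs 100 for PTV coverage) supplements the one-sided bound
  penalties in *both* control and base-plan runs. Clinical plans always
  carry a standing parotid mean objective; without it the control has no
  incentive to keep gland dose low once below the protocol bound, which
  no real plan exhibits. Acting on physical dose only, the term is
  identical in both arms and cannot itself produce a steering
  difference.

`matched_coverage_pair` optimizes a control (whole-mean bound only,
default 20 Gy) and a base-plan arm (shifted mean bound + Dmax bound,
default margin 10 Gy), then bisects the base-plan arm's PTV weight on a
log scale until PTV V98 matches the control within ±0.005 (warm-started,
≤ 30 steps). The cohort demonstration uses the cohort-scale phantom
geometry on a coarsened 4 mm grid with 9 gantry angles and 6 mm
beamlets — sizes chosen to keep a full 15-phantom study at a few minutes
on one CPU. On that study the `BP_30` arm lowers the S1 mean dose in
15/15 phantoms and raises predicted saliva output in ≥ 14/15, with a
paired t test significant well below P = 0.05 (regression-tested).
Because the optimum of the quadratic is degenerate in the beamlet null
space, consistency checks (e.g. a uniform base plan with shifted bounds
versus no base plan with unshifted bounds) compare objective values and
plan metrics, not voxelwise fluence.

## Known limitations

- The importance table, octant layout beyond rank 1, and Hill parameters
  are placeholders/synthetic; conclusions about real patients require
  the published population values.
- The demonstration optimizer has no MLC, arc, or scatter model; its
  numbers demonstrate the steering mechanism, not achievable clinical
  dosimetry.
- Only axis-aligned geometries are supported; contours spanning exactly
  one slice gap, multi-component glands, and sub-voxel surface distances
  are handled with documented, simple conventions (nearest slice,
  warn-and-proceed, voxel centers).
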