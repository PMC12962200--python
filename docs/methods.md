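# Methods

This note documents the models, numerical choices and limitations behind
`ptxshim`: what the synthetic-data generator emulates, how the constrained
shim optimisation works, how the metrics are defined, and which design
decisions were genuinely open.

## Synthetic field model

The simulator produces, per subject, an ellipsoidal head phantom with
nested head / brain / ROI masks and one complex relative transmit-field
volume per coil element.  It is geometric-phenomenological, not an
electromagnetic solver: the package exists to exercise constrained
optimisation and evaluation metrics, not field physics.

* **Grid.** Default 48×48×32 voxels at 4 mm isotropic (192×192×128 mm),
  centred on the world origin.  This desk-scale lattice keeps a full
  19-train / 6-validation study with a 19-point convergence curve in the
  range of minutes on one CPU; all operations are resolution-agnostic.
* **Phantom.** Head semi-axes are 75% of the grid half-extent, jittered
  ±4% per subject; the brain is a concentric 82%-scaled ellipsoid.  The
  shimming ROI keeps the superior 60% of brain voxels (by z-percentile),
  emulating a supraorbital-cerebrum target that excludes cerebellum and
  temporal lobes.
* **Fields.** For element c at position p_c, the in-head magnitude is
  1/(1 + (d/D0)²) with d = |r − p_c| and D0 = 70 mm (inverse-power decay
  with a smooth floor), and the phase is a travelling wave −2πd/λ plus a
  per-channel offset.  The default λ = 90 mm is short relative to the
  head, forcing the strong multi-channel interference characteristic of
  ultra-high field; an unshimmed CP combination then shows ~50–60% NRMSE
  over the ROI.
* **Channel phase offsets.** The offset is the element azimuth plus a
  small random deviation (σ = 0.15 rad).  The azimuthal base term models
  the rotation of a loop element's transmit-field orientation with its
  position on the ring — the property that makes a circularly-polarised
  mode (phases = −azimuth) constructive on the coil axis.  A fully random
  per-subject offset would erase the cross-subject phase structure that
  universal shimming exploits, so only the deviation is randomised.
* **Coil geometry.** 16 elements in two rings of eight on a 110 mm-radius
  cylinder, the second ring azimuthally interleaved by 22.5°.  The ring
  heights default to z = 20 mm and 60 mm, placing both rings over the
  cerebrum.  This choice is deliberate: with rings symmetric about the
  head centre, the superior-slab ROI is illuminated almost solely by the
  upper ring, and homogenising it demands per-channel weights near 0.5 —
  the α band [0.8, 1.3] and the 0.35 weight cap cannot then be satisfied
  simultaneously by any solution.  Real head arrays cover the crown, and
  the in-vivo problem this package models is one where converged
  constrained solutions exist; the ring placement was selected (by a
  feasibility scan over candidate geometries) so the default study
  conditions reproduce that regime, with slack, across pose-jittered
  subjects.
* **Population.** Subject i derives all randomness from fixed arithmetic
  on the base seed (`seed + 1000·i`, `+1`, `+2` for phantom, fields, and
  pose/wavelength respectively), so any subject regenerates
  independently.  Pose jitter is Gaussian with σ = 3 mm translation and
  3° rotation per axis — small, reflecting consistent head positioning
  within a tight-fitting coil — and the wavelength varies ±3% between
  subjects as a proxy for tissue variation.

What the generator does **not** emulate: realistic anatomy, conductivity
and permittivity structure, element coupling, SAR, receive fields, or
measurement noise in B1+ mapping.  Passing tests therefore demonstrate
the correctness and robustness of the optimisation and metrics under a
plausible interference structure, not performance on in vivo data;
absolute NRMSE levels here (≈10% subject-specific, ≈13% universal, ≈60%
CP on the ROI) are comparable in ordering but not in magnitude to
in vivo values.

## Constrained shim optimisation

All solvers share one smooth real parametrisation.  Phase-magnitude mode
optimises x = [Re u; Im u] ∈ R^{2C} with w = u/‖u‖ (the unit-norm
constraint disappears into the parametrisation); phase-only mode
optimises the C channel phases with magnitudes fixed at 1/√C.  Every
cost and constraint is invariant to the scale and global phase of u.
Gradients are analytic throughout (Wirtinger calculus folded into the
real parametrisation) and were verified against finite differences.

* **Costs.**  Efficiency: f = ‖u‖ / mean_region |B u| (equals 1/mean
  |B w| at unit norm); lower is better.  Coefficient of variation:
  f = std/mean of |B w| over the region.  For the universal objective
  F = sqrt(Σ_s f_s²), both choices keep f_s nonnegative, which the L2
  composition requires.
* **Flip-angle bounds.**  α(r) is the region-mean-normalised |B1+|;
  the bounds α ∈ [0.8, 1.3] are interpreted relative to that mean,
  because relative field maps carry arbitrary units and only a relative
  bound is well-posed.  Subject-specific solutions face them as hard
  constraints; the universal solver converts them to quadratic hinge
  penalties with weight 100 per subject (joint hard feasibility across a
  whole database may be empty).
* **Weight cap.**  |w_c| ≤ 0.35 is enforced as a hard constraint in both
  modes, tightened internally by the 1e−6 feasibility tolerance so
  accepted solutions land strictly below the cap.
* **Solver.**  Per start: (1) an L-BFGS-B warm-up on the cost plus hinge
  penalties (μ = 10³); (2) if the α band is still violated, a
  feasibility homotopy that minimises the pure hinge violation over a
  schedule of α bands tightening from 2.5× the target width down to the
  target; (3) an SLSQP polish minimising the cost subject to smooth
  constraint aggregates.  The per-voxel α bounds are aggregated with a
  log-sum-exp soft maximum of sharpness k = 1000: the soft max
  overestimates the true maximum by at most ln(M)/k, so feasibility of
  the smoothed constraint implies feasibility of the exact one (the
  aggregate is conservative, never permissive).
* **Starts.**  Deterministic starts are always kept: any warm start
  (e.g. the previous increment of an expanding-database fit), a
  homogeneity-first start obtained by descending the CV cost (the CV
  basin is exactly the neighbourhood where the α band is satisfiable),
  a phase-matched start (conjugate of the mean channel phasor), and the
  CP mode when the geometry is known.  `n_restarts` adds uniform random
  phase starts beyond these.  Defaults: 32 for one-off subject fits,
  4–8 inside population studies, and 2 per increment of the convergence
  study, where the warm start from the previous increment dominates and
  extra restarts were never observed to change the optimum.
* **Selection and ties.**  Among feasible candidates (violations within
  1e−6), lowest cost wins, ties broken by smaller max |w_c|.  If no
  start reaches feasibility the best-penalty solution is returned with
  `converged=False`; it is never silently accepted as feasible.
* **Conventions.**  Returned vectors are unit-norm (to 1e−9) with the
  global phase rotated so channel 1 is real nonnegative; serialisation
  uses per-channel (magnitude, phase-in-degrees) pairs.

A consequence of the hard/soft asymmetry worth knowing: on a single
subject the universal solution may attain a *lower* raw efficiency cost
than the hard-constrained subject-specific one, by under-flipping a few
voxels that the hard constraints forbid.  The strategy ordering that
holds robustly — and that the tests assert — is in median validation
NRMSE: subject-specific ≤ universal ≤ CP, and universal ≤ CP in cost.

## Evaluation metrics

NRMSE over a region is 100·sqrt(mean (α−1)²) with α calibrated so the
*calibration* region mean is 1; when evaluation and calibration regions
coincide this equals the coefficient of variation, which is documented
rather than hidden.  Whole-brain rows in the strategy table are
re-calibrated to the whole-brain mean and labelled (`calibration` column)
to keep both readings available.  The median is the cross-subject
aggregator everywhere.  Field histograms use a fixed [0, 2] range with
50 bins for cross-subject comparability and report the fraction of
voxels below 0.5 (a "very low B1+" marker).  The convergence study adds
training datasets strictly in acquisition order, warm-starting each
increment, and reports CP-mode and subject-specific medians as reference
lines; a failed increment is flagged in the curve, not fatal.  Because
single-run curves are noisy, the decrease claim is asserted on the
seed-averaged endpoint versus the seed-averaged start over ≥5 seeds, not
per-seed monotonicity.

## Morphometry

MJS class weights are the per-voxel mean fractions (A_n + B_n)/2
renormalised to sum to 1 over classes; "mean fraction" could also be
read as a global weight, but the per-voxel reading keeps MJS within
[0, 1] voxelwise and reproduces both endpoints (1 for identical
composition, 0 for disjoint one-hot voxels).  Class terms with
A_n = B_n = 0 contribute zero with zero weight, avoiding 0/0.  Masked
voxels where one map carries no tissue at all are excluded (NaN) and
counted in the log.  The companion view 1 − MJS is exactly one minus the
map.  Degenerate paired t-tests follow explicit conventions: identical
samples give p = 1 with a flag, zero-variance nonzero-mean differences
give p = 0.  Region comparisons report unadjusted p-values (flagged as
such) with an optional Benjamini–Hochberg column; regions present in
only one condition are excluded and logged.  Volume tables follow a
small CSV contract (long `region, hemisphere, volume_mm3` or wide
`region, left_volume, right_volume`) rather than any segmentation tool's
output dialect.

## Problem sizes

Defaults used by the tests and the acceptance script: 48×48×32 grid,
16 channels, ROI ≈ 6×10³ voxels; populations of 25 subjects split
19 train / 6 validation; five seeds for the ordering and convergence
properties; 64-level phase grids for the 2–3-channel exhaustive oracles;
10⁴ replicates for the paired-t null-uniformity check.

## Known limitations

* The field model has no electromagnetic validity; constraint-set
  geometry (which α bands are feasible at which caps) depends on the
  phenomenological decay and ring placement, and was tuned only to the
  qualitative in-vivo regime.
* The optimiser is a local multi-start method; global optimality is
  checked only against exhaustive oracles at ≤3 channels.
* Phase-only solutions generally cannot satisfy the default α band on
  these fields (fixed magnitudes lack the degrees of freedom) and are
  returned flagged `converged=False`; their costs remain comparable.
* SAR and vendor-specific constraints, dynamic pTx pulse design, raw
  scanner-data reconstruction, registration and segmentation itself are
  out of scope; the morphometry module consumes segmentation outputs.
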