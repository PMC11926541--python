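# Methods

## Problem and scope

In short-course pelvic radiotherapy of rectal cancer the clinical target
volume (CTV) is delineated with the bladder full, but the daily bladder is
usually smaller than at simulation. A plan built once on the simulation
anatomy (adapted each day only by a couch shift) then underdoses the target
tissue that moves into the space the bladder vacated, while full daily
re-planning (adapt-to-shape, ATS) is accurate but slow. The
library-of-reference-plans (LoRP) strategy pre-computes plans for a family
of bladder-filling states and selects one per fraction from the daily image.

This package is an *in-silico* implementation of that strategy: every input
is synthetic, every dose is produced by an explicit surrogate engine, and
the purpose is to make the strategy's geometric and decision logic — wall
Booleans, margining, selection, classification, cohort comparison — exact,
testable, and reproducible. It does not model MR imaging, deformable
registration, or a clinical optimizer, and its cohort rates characterize
the synthetic conditions, not any patient population.

## Coordinate convention

Axes are (x, y, z) = (right→left, anterior→posterior, inferior→superior);
the "posterior wall" of a mask is its maximal-y extent and the "superior
wall" its maximal-z extent. Voxel (i, j, k) has world coordinate
`origin + index·spacing` (voxel centers). The default grid is 96³ voxels at
2 mm isotropic spacing (192 mm field of view per axis).

## Synthetic anatomy

Organs are analytic solids rasterized on the grid; no image intensities are
simulated (plan selection consumes masks, not images):

* **bladder** — ellipsoid, semiaxes (30, 32, 30) mm, volume ≈ 121 cm³;
* **ctv_envelope** — the clinical CTV *before* bladder accommodation: an
  elliptical cylinder along z whose anterior boundary reaches ≈18 mm into
  the full bladder (the anterior margin that absorbs filling variation);
* **intestine**, **colon** — tubes superior-anterior to the target;
* **femur_l/r** — spheres at x = ±62 mm (the bony registration surrogate);
* **perineum** — inferior ellipsoid slab.

Per-patient variability is a 2 mm-sd jitter of organ centers, seeded.

## Inter-fraction variation model

The daily anatomy is derived from the simulation anatomy by three seeded
mechanisms, in this order:

1. **Bladder wall retraction.** Posterior- and superior-wall retractions are
   drawn from truncated normals N(1.2, 0.6) cm clipped to [−1, 3] cm and
   applied with the same directional wall operators the library uses. The
   defaults are calibrated analytically so the daily/simulation bladder
   volume ratio has median ≈ 0.5: a chord cut of depth d removes
   `∫max(L−d,0)` over columns, and two sequential ≈12 mm cuts of the default
   ellipsoid each retain ≈72 % of the volume (0.72² ≈ 0.52). A 200-scenario
   Monte-Carlo test checks the realized median lies in [0.40, 0.60].
2. **Couch setup offset.** Per-axis N(0, 3 mm), rounded to integer voxels;
   the daily anatomy reuses the simulation grid and the true translation is
   stored, so registration is testable against ground truth without
   resampling error.
3. **Gas event** (probability 0.08 per fraction). The anterior third of the
   target envelope is displaced 10 mm anteriorly (union, posterior part
   unchanged). This reproduces the out-of-library failure mechanism — a
   target pushed beyond the reach of every pre-planned CTV — without
   modeling gas pockets explicitly.

What the generator does *not* emulate: deformable organ shape change,
rotations, intra-fraction motion, delineation uncertainty, or density
changes. Passing tests therefore demonstrate the strategy's logic under
controlled translations and wall retractions only.

## Wall Boolean operators

Contraction of a wall by d is `mask ∩ translate(mask, d toward the wall's
interior)`; expansion is `mask ∪ translate(mask, d outward)`. The AP
operator is applied first, then SI (mixed compositions need not commute on
non-convex shapes, so the order is fixed). Along its own axis each operator
moves only the named wall: on any mask whose y-columns are intervals, the
anterior bound of every column is unchanged by the AP operator. The global
anterior/inferior extremes of a 3D convex body can still recede under the
*other* axis' contraction (the y-extreme lives in the z mid-plane); tests
assert the per-axis property. Shift distances are rounded to integer voxel
counts — exact for the default 1 cm steps on 2 mm spacing.

The library grid is {−1, 0, +1, +2} cm on each axis (expansion negative),
16 variants including the original, nested under the componentwise
contraction partial order by construction.

## CTV, PTV, margin

Each variant's CTV is the envelope minus the bladder variant (set
difference), so a more contracted bladder frees more envelope and CTVs nest
oppositely to the bladders. The PTV is the CTV plus a 6 mm isotropic margin:
a voxel belongs to the PTV iff its center lies within 6 mm (boundary
inclusive) of some CTV voxel center, computed with a Euclidean distance
transform and verified against an exhaustive KD-tree distance oracle on
small grids.

## Surrogate dose engine

With s(x) the signed Euclidean distance to the PTV surface (negative
inside), plateau extension p = 1 mm and penumbra width w = 8 mm:

    D(x) = Rx                      s ≤ p
    D(x) = Rx·(1 − (s − p)/w)      p < s ≤ p + w
    D(x) = 0                       otherwise

Rx = 25 Gy (5 × 5 Gy). The engine is deliberately beam-free: the plan-library
logic is dose-model-agnostic and every property claimed in the tests is a
property of this surrogate. Consequences worth noting: dose never exceeds
Rx, so the intestine/colon V27.5Gy criteria rows can never fail here (kept
for protocol fidelity); and the planning PTV always has V25Gy = 100 %.
The virtual couch shift resamples dose at x − t (trilinear, zero outside);
integer-voxel shifts are exact array shifts.

## Registration and plan selection

Translation-only registration aligns the femur-union centroid and refines
over a ±2-voxel integer search maximizing femur overlap — exact for the
integer-voxel ground-truth offsets the generator produces. Selection maps
each library bladder into the daily frame by that translation and keeps
entries whose posterior and superior walls do not exceed the daily
bladder's (global wall extents, not voxelwise containment — the looser,
wall-based reading; anterior and inferior walls are unconstrained). Among
admissible entries the largest bladder volume wins (equivalently the
least-contracted entry, keeping the CTV as small as safely possible);
ties break toward smaller |ap|+|si|, then smaller ap. If nothing is
admissible the most-contracted entry is returned flagged `out_of_library`;
such fractions proceed and may fail the criteria, which is the observable
the flag preserves.

## DVH metrics and classification

Metrics are computed exactly from voxel doses over voxel centers inside
each mask; the 0.1 Gy-binned cumulative curve exists only for export.
D_1cm³ interpolates linearly between sorted voxels at the 1 cm³ boundary
and falls back to the mask minimum (with a warning) for structures smaller
than 1 cm³. The default criteria table (shipped as YAML) has 10 rows over
7 structures with per-protocol and variation-acceptable bounds; `at_least`
rows pass at equality, `less_than` rows fail at equality. Overall class:
per-protocol iff all rows per-protocol; acceptable iff all rows at least
variation; else unacceptable. Target rows are always evaluated on the
*daily* ground-truth PTV (envelope minus daily bladder, margined), for
every strategy.

## Strategy analogs

* **lorp_atp** — register, select, shift the selected entry's reference
  dose by the registration translation;
* **catp** — shift the original (0, 0) reference dose by the same
  translation, no reselection (the clinical segment re-optimization step is
  deliberately omitted);
* **ats** — conformal dose computed directly on the daily true PTV.

With zero variation all three coincide. At cohort level the acceptable-rate
ordering ats ≥ lorp_atp ≥ catp is asserted as a property; the simulated
percentages themselves depend on the synthetic geometry and variation model
and are reported, not asserted.

## Cohort harness and statistics

The default design is 10 patients × 5 fractions (50 fractions), fully
seeded: per-patient and per-fraction seeds are spawned from one
`SeedSequence`, so reruns are bit-identical. Fractions are pooled across
patients in summaries and comparisons. Paired comparisons test the paired
differences for normality (Shapiro–Wilk, α = 0.05) and use the paired
t-test if normal, otherwise the Wilcoxon signed-rank test (zero-differences
discarded, the routine's `wilcox` convention); all-tied pairs short-circuit
to p = 1, and fewer than 5 pairs skips the test with a warning.

## Problem sizes and numerical choices

Default runs use the 96³ × 2 mm grid: a 16-entry library builds in ~7 s and
the 50-fraction, three-strategy cohort in ~90 s on one core. Unit and
property tests use 24³–48³ grids where the full grid adds nothing.
Admissibility comparisons use a 1 µm tolerance so exactly-equal walls are
admissible. Degenerate inputs: empty CTV → empty PTV; empty bladder variant
→ admissible with volume 0 (never selected over a nonempty entry); shift
consuming the whole mask → empty, allowed.

## Known limitations

Surrogate dose only (no beams, no optimizer, no electron-density effects);
translations and wall retractions only (no deformation or rotation);
single-phantom family geometry; criteria rows involving dose levels above
the prescription are vacuous under the surrogate; clinical timing and
workflow effects are out of scope.
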