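# Methods

This note documents the models, parameters and numerical choices behind
`biopsim`, and what the synthetic cohort does and does not emulate.

## Coordinate frame and units

All geometry is in millimetres. x is lateral (patient left positive), y is
anterior–posterior (anterior positive), z runs along the base–apex axis
(base positive), with the origin at the gland centre. Volumes are reported
in ml (1 ml = 1000 mm³).

## Synthetic cohort

### Gland and lesion geometry

The gland is an axis-aligned ellipsoid with fixed axis ratios
width : height : length = 1 : 0.70 : 0.80 (typical adult prostate
proportions), scaled to the sampled volume. The urethra is modelled as a
z-parallel line slightly posterior of centre (y = −0.10·b); the coronal
plane through it separates the anterior from the posterior zone. The anus
reference point, from which transrectal trajectories fan, sits 30 mm
posterior and 30 mm caudal of the gland surface.

Lesions are ellipsoids with randomized orientation and per-lesion semi-axis
ratios b/a ~ U(0.55, 0.95) and c/a ~ U(0.35, 0.75). Real tumour foci are
irregular and sprawling; an equal-volume ellipsoid is more compact and
therefore *easier* to intersect with a needle, so simulated hit rates are
an upper bound on histology-shaped lesions of the same volume. The
eccentricity ranges temper, but cannot remove, this bias — a caveat for
interpreting absolute (as opposed to between-strategy) detection numbers.

Lesion centres are rejection-sampled uniformly within the gland (candidate
radius shrinking over attempts so large foci drift toward the centre),
subject to (a) the whole lesion surface lying within the capsule at a 5 %
scaled-distance tolerance and (b) the centre lying on the sampled zone's
side of the urethral plane (the zone constraint is released in the second
half of the attempt budget; the label then follows the centre). A spec that
cannot be satisfied within the attempt budget raises `InfeasibleSpecError`
rather than silently distorting the geometry. The index (largest) lesion is
capped at 25 % of the gland volume so that placement remains feasible
across the gland-volume range.

### Distributions

All volume and count distributions are truncated lognormals; parameters
live in `CohortSpec`, not in code. Log-space SDs were fitted from published
summary statistics of a 107-specimen whole-mount series:

| quantity | median | σ (log) | truncation | fit source |
|---|---|---|---|---|
| gland volume (ml) | 50.2 | 0.31 | [26.8, 127.7] | median + range (range ≈ ±2.55σ sample extremes at n≈107) |
| lesions per gland | 5 | 0.60 | [1, 21] (rounded) | median + range |
| index lesion (ml) | 1.215 | 0.92 | [0.015, 13.242] | median + mean (1.895) and CV (1.148) agree on σ ≈ 0.92 |
| non-index lesion (ml) | 0.019 | 1.71 | [0.001, 1.842] | median + mean (0.082); CV fit concurs |

Zone probabilities are anterior 415/665, posterior 250/665; the gland-level
Gleason mix is {≤6: 0.57, 7: 0.35, ≥8: 0.08}, assigned to the index lesion
(non-index foci carry ≤6 — intra-lesion grade structure is out of scope).
Non-index volumes are additionally capped below the index volume and the
total tumour burden below half the gland volume.

### False-positive targets

Imaging false positives are modelled as additional glands whose only
"lesion" is a benign region (≥ 0.2 ml, drawn from the index distribution):
it is an eligible target and is planned against like any lesion, but
contributes zero cancer length. With rate r, m = round(n·r/(1−r)) benign
models are appended so the fraction of targeted sessions aimed at a benign
region is r (107 cancer glands at r = 0.34 → 55 benign models, 162 total).
The source series reports 141 biopsied prostates at that rate; no simple
formula reproduces 141 from 107 and 34 %, so the rate and the cohort size
are deliberately independent knobs. At r = 1 the cohort consists solely of
benign-target glands.

## Contour stacks and reconstruction

`emit_contour_stack` step-sections a model at slice planes placed at the
centres of `slice_thickness` (default 5 mm) slabs spanning the gland's
axial extent; each plane carries exact elliptical cross-sections as 64-gon
polygons. Lesions thinner than one slice can miss every plane; they are
listed in `missing_structures` and warned about, never silently dropped.

Reconstruction inverts this: slices are rigidly translated in-plane so
capsule centroids align to the midgland reference (the slice of maximal
capsule area; slices lacking a capsule are flagged and their translation
interpolated from neighbours), then each structure's per-slice signed
distance field (Euclidean distance transform, mm) is interpolated along z
and thresholded at zero. Between slices the interpolant is a monotone cubic
(PCHIP) through the per-slice distances — with only two slices this is the
classical linear signed-distance blend (two stacked circles of radii 10 and
≈0 give a mid-slice radius of ≈5). Beyond the terminal slices the structure
is capped over half a slice thickness by a quadratic distance taper (an
observed structure can extend at most to the next cut face). On an
r = 10 mm sphere sectioned at 5 mm this recovers the analytic volume to
well under 1 %; piecewise-linear axial interpolation alone would
underestimate it by ≈6 %. Structures present only on non-adjacent slices
are reconstructed per contiguous run with a warning. Default voxel spacing
is 0.5 mm (below lesion scale, modest memory); lesion masks are clipped to
the gland dilated by a 1 mm containment tolerance.

Fixation shrinkage is reversed after reconstruction by scaling the voxel
spacing by the linear factor (default 1.10, i.e. a 33.1 % volume increase).
Because the correction is isotropic, the order relative to interpolation is
immaterial for volumes; coordinates scale about the model origin.

## Core geometry

A biopsy core is a zero-width segment of effective (notch) length 17 mm —
a typical 18-gauge device; the value is configurable and reported in all
outputs because every MCCL saturates at it. Needle diameter and tissue
deformation are ignored. Cancer length is computed two ways: exactly, by
solving the line–ellipsoid quadratic per lesion and merging the clipped
parameter intervals (so overlapping foci are counted once, as a union), and
by dense point sampling at half the voxel spacing for voxel-backed models.
The two routes agree within 2 % or 0.2 mm on random ellipsoids and serve as
mutual oracles in the tests. Both the total intersected length and the
longest contiguous run are computed; the total is primary, since 5-mm
step-section histology cannot resolve contiguity along a needle track. A
core is positive when its cancer length exceeds the positivity threshold
(default 0 mm — any intersection; configurable, e.g. 0.5 mm, for
sensitivity analyses).

## Biopsy schemes

**TRUS12.** Twelve cores are placed from anatomy alone:
left/right × base/mid/apex × medial/lateral, with nominal midpoints at
gland-fraction coordinates (lateral fractions 0.35/0.70 of the semi-width,
axial fractions ±0.55/0, depth 0.45 of the semi-height into the posterior
gland) and trajectories from the anus reference. The pathology is never
read — deleting every lesion leaves the plan unchanged (tested). Per-axis
probe/insertion variability (SD 2 mm, a modelling choice: the source
describes the concept but not the magnitude) is re-drawn every repetition.

**Targeted.** Cores are constrained to a 5-mm template lattice anchored
with the urethra at column D, row 2.0. For the largest eligible target
(volume ≥ 0.2 ml, true or false-positive), every lattice column's chord
through the imaged target shape is evaluated; the k best positions are
taken greedily (ties: distance to the target centroid, then lexicographic
grid order), and each core's axial extent is centred on its chord — the
"deepest part" of the lesion. Because distinct lattice columns are disjoint
sampling lines, the greedy choice equals the exhaustive-search optimum;
this is verified against explicit enumeration. If fewer columns intersect
the target than k, remaining cores stack on the best position with a
warning. Perfect segmentation of true targets is assumed; imaging and
fusion misalignment are absorbed into the registration error term.
Multi-lesion glands allocate all targeted cores to the index target
(typical practice takes 3–4 cores per lesion; multi-target allocation is a
config extension point).

## Targeting error

Displacements are zero-mean normal with independent components in three
orthogonal directions, applied as a pure translation of the core midpoint
(no bending). Two modes:

* `combined` (default): one total displacement per core; the summed
  per-axis variance equals the set total variance `total_sd²` = 25 mm² at
  the 5-mm default. Applied to all strategies for comparability.
* `components`: deflection (per-axis SD 3 mm) and registration (per-axis SD
  3 mm, targeted cores only unless configured otherwise) sampled separately
  and rescaled to the set total — which deliberately exceeds the additive
  component variance, following the source error budget.

`sd_convention` selects how `total_sd` maps to axes. The default,
`"vector"`, makes the *summed* per-axis variance equal `total_sd²`
(per-axis SD 5/√3 ≈ 2.89 mm). The alternative, `"per_axis"`, gives every
axis SD `total_sd` — the reading under which the published comparison
"set total variance 25 mm² exceeds additive 9 + 9 mm²" is arithmetically
coherent axis-by-axis, and under which (at full cohort scale) targeted
sampling never lifts a clinically insignificant case into the high-risk
class, while with the tighter `"vector"` dispersion a borderline
0.2–0.5 ml target hit by 3–4 deliberately aimed cores often crosses the
≥ 50 %-positive threshold. Both behaviours are pinned by tests; the
choice matters for absolute hit rates and is exposed in config.

Repetitions: TRUS plans are re-drawn per repetition (anatomic jitter);
targeted plans are planned once and perturbed at realisation. Seeding uses
`numpy` `SeedSequence` substreams per (model, strategy), so any cohort
subset reruns bit-identically under the same master seed.

## Risk metrics and statistics

A session is high risk when MCCL ≥ 6 mm and/or ≥ 50 % of deployed cores are
positive (boundaries inclusive). Clinically significant disease: any true
lesion ≥ 0.5 ml and/or Gleason ≥ 7. Sensitivity is per-repetition detection
averaged over repetitions and then over the stratum's cancer-bearing models
(the saturating "detected in any repetition" rule is available but not the
default, since it converges to 1 as repetitions grow); benign-target models
are excluded from denominators, and an empty stratum raises rather than
returning a silent 0/0.

Case-level risk aggregation over repetitions is configurable. The default
(`"mean"`) applies the thresholds to the per-case mean MCCL and mean
%-positive — one classification per case, consistent with reporting a
single risk class alongside per-case summary statistics. The alternative
(`"majority"`) classifies each repetition and takes the >0.5 majority. The
per-repetition table is always emitted so any other rule can be applied
post hoc. Summary tables report mean ± SD, median and 90th percentile
(inclusive linear-interpolation convention) of per-case means, per stratum
(all / significant / insignificant) and strategy.

Between-strategy comparisons pair per-case means by model and report the
paired Student t test plus two readings of a "paired KS test" (the exact
variant in the source literature is ambiguous): the two-sample KS statistic
on the matched per-case values, and a two-sample KS of the paired
differences against their sign-flipped mirror (a symmetry test). Raw
p-values, α = 0.05, no multiplicity correction. Fewer than 3 pairs is
refused.

## Problem sizes and determinism

Default configuration: 107 cancer glands (+55 benign targets), 500
repetitions, strategies TRUS12/TARGETED_3/TARGETED_4. The engine is
vectorised over repetitions × cores × lesions, so the full default run
completes in seconds on one CPU; the test suite exercises the full-scale
cohort at 100 repetitions and 1,000-draw distribution checks. All results
are bit-reproducible given the config and master seed, and every artifact
embeds the config hash and seed.

## Known limitations

* Ellipsoidal lesions overstate the compactness of real foci; absolute
  sensitivities and positive-core fractions are optimistic, and
  borderline-size targets are easier to hit than their histologic
  counterparts. Between-strategy contrasts are far more robust than
  absolute levels.
* Intra-lesion Gleason pattern structure, mpMRI appearance/conspicuity,
  PSA-based stratification, needle bending, pubic-arch interference and
  probe-pressure deformation are out of scope.
* Slice alignment is translation-only (rotation is an extension point);
  registration of histology to in-vivo anatomy beyond isotropic shrinkage
  is not modelled.
* Reconstruction of sub-slice-thickness lesions from 5-mm stacks is
  intrinsically lossy; such structures are flagged rather than recovered.
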