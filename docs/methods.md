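# Methods

This note documents the models, conventions, and numerical choices
behind `fixmap`, and what the synthetic-data tests do and do not
establish about real data.

## Coordinate and data conventions

All spatial quantities are degrees of visual angle in an image-style
frame: origin at screen center, x rightward, y **downward**. This
matches eye-tracker exports and raster conventions; "upper face"
therefore means negative y. Fixation reports are tab-delimited with one
row per fixation (participant, trial, phase, orientation,
start_position, face_id, ordinal, x, y, onset_ms, duration_ms); AOI
files are tab-delimited rectangles (face_id, label, x_min, y_min,
x_max, y_max) with one `image` row per face carrying the stimulus
bounds. The seven AOI labels are left/mid/right eye (mid = bridge of
the nose), left/right half-nose, and left/right half-mouth; `mid_eye`
maps to itself under mirror reflection while the lateral labels swap.

## Start-position geometry

Left and right start positions are the circumcenter of the same-side
eye, half-nose, and half-mouth AOI centers, computed in closed form as
the intersection of two perpendicular bisectors; a triangle area below
10⁻⁹ deg² raises a degenerate-geometry error naming the face. Upper and
lower starts lie on the perpendicular bisector of the two eye
(respectively half-mouth) centers, at a target distance equal to the
mean of the left/right start-to-anchor distances; a target at or below
half the anchor separation is infeasible and raises. Of the two
bisector solutions, `upper` takes the one farther from the mouth
midpoint and `lower` the one farther from the eye midpoint — "forehead
side" and "chin side" expressed in face-intrinsic terms, so the rule
survives face inversion unchanged. This branch rule is a declared
package convention, one of several defensible choices. The center start
is the midpoint of the two half-nose centers.

Alignment to the common reference frame is translation-only; the
translation minimizing the sum of squared differences between a face's
seven AOI centers and the across-face mean centers is, in closed form,
the mean center offset.

## Latency-to-first-saccade from fixation reports

Fixation reports come in two dialects and both are supported. If the
ordinal-1 fixation spans stimulus onset (onset_ms ≤ 0, the residual
start-dot fixation), the first saccade begins when it ends: latency =
onset + duration. If ordinal 1 is the first post-saccadic fixation on
the stimulus (onset_ms > 0), saccade flight time is not recoverable
from a fixation report and latency = that fixation's onset. The
synthetic generator emits the second dialect.

## The synthetic scanpath generator

The generator emulates the statistical regularities of start-position
face-viewing data; its defaults are declared constants, not estimates:

- **Faces.** A canonical layout sized from a 10°-wide face on a
  10 × 12° image; each face translates every AOI rectangle by i.i.d.
  N(0, 0.15²) per axis. Layouts with unsolvable start positions are
  resampled (bounded retries). The canonical AOI coordinates were fixed
  once, at design time, so that all five start positions are solvable
  and sit at plausible peri-facial distances (≈ 2.5–4° from the face
  center), with lateral starts just outside the cheeks.
- **First fixation.** Gaussian (sd 0.7°) at the face center, shifted
  κ = 0.5° *toward* the start position (the "slight tendency toward the
  start" regularity).
- **Fixations 2–5.** A mixture of Gaussians (sd 0.8°) anchored on the
  seven AOI centers with eye-favoring weights
  (.22/.14/.22 eyes, .12/.12 nose, .09/.09 mouth), shifted δ = 1.5°
  toward the side of the face *opposite* the start position. δ has no
  published magnitude; 1.5° was chosen as a clearly visible but not
  saturating displacement relative to the ≈ 3.8° eye separation, and is
  also the planted-effect size used in the power calibration.
- **Counts.** Trials have min + (geometric − 1) fixations capped at 10;
  the study-phase minimum of 5 exercises the first-five rule, the
  test-phase minimum of 3 reflects the shorter viewing typical of brief
  test presentations.
- **Timing.** Durations per ordinal: means (150, 280, 300, 310, 310) ms,
  sd 60 ms, floor 30 ms — the first fixation markedly shorter. Latency
  to first saccade: mean 180 ms (sd 40) for peripheral starts, 280 ms
  (sd 60) for the center start, floor 80 ms.
- **Behavior.** Equal-variance signal detection with criterion midway
  between the old/new evidence means: P(hit) = Φ(d′/2),
  P(false alarm) = Φ(−d′/2); defaults d′ = 2.0 upright, 1.2 inverted.
- **Inversion.** Inverted trials are generated in the inverted face's
  own frame: the geometry is reflected about the image's horizontal
  midline first, then landmarks and start positions are taken from the
  reflected face.
- **Reproducibility.** One root seed; per-participant streams are
  spawned from it, so regenerating any participant subset reproduces
  exactly.

The null-dataset builder zeroes κ and δ and emits two conditions (left
vs right start labels) with *identical* per-ordinal generating
distributions — exchangeable by construction. The effect-dataset
builder additionally shifts the left-start condition's fixations 2–5 by
δ toward the right side of the face.

What the generator does **not** emulate: saccade kinematics and
undershoot, blinks, calibration drift, duration–location coupling,
serial dependence between successive fixation locations beyond the
shared condition mean, face-specific feature saliency, and
participant-level heterogeneity in bias magnitude. Calibration results
on synthetic data therefore establish the *statistical validity and
sensitivity of the inference machinery* under the stated model, not
properties of any particular human dataset.

## Density maps

Each fixation contributes an isotropic Gaussian pdf (σ = 0.3°)
evaluated at pixel centers, truncated at 4σ; a per-trial map's integral
equals its fixation count within the declared 10⁻³ truncation
tolerance. Fixations are never duration-weighted. Maps are averaged
across trials within participant and then across participants, which
keeps unbalanced designs well-defined. The raster default is 0.05°/px
over the image bounds padded by 1° (configurable; the cluster null is
recomputed per grid, so inference is resolution-robust). Mass
normalization (each fixation integrates to 1) was adopted over
amplitude normalization; with a common σ the two differ only by a
global constant and mass gives maps in interpretable fixations/deg²
units. Out-of-image fixations are clamped to the nearest image-edge
point *before* rasterization so all trials keep equal fixation counts.

## Permutation inference

Stratified exchangeability: locations are reassigned between the two
contrasted conditions only within (participant × ordinal) strata,
preserving per-condition counts, independently per participant and
iteration. The implementation exploits linearity: a group difference
map is a fixed sparse matrix of per-fixation Gaussian stamps times a
per-fixation weight vector (+1/(P·n_trials_A(p)) for condition-A slots,
−1/(P·n_trials_B(p)) for B), and a relabelling only permutes the weight
vector within strata. This is exactly equivalent to re-rasterizing
every iteration. When all N resampled maps fit a memory budget
(default 512 MB) significance of the retained cluster-null maps is
resolved by per-pixel order statistics (`np.partition`); otherwise a
streaming path bounds memory by the retained subset. Both paths are
bit-identical (tested).

Pixel p-values are sign-adaptive, add-one, with ties counted toward the
null. Note a structural property of this published rule: each pixel is
tested in one of two one-sided directions at α = 0.01 *each*, with no
two-sidedness correction, so for a pixel with a continuous symmetric
null the rejection probability is ≈ 2α, not α. The calibration battery
measures ≈ 0.012 averaged over face-region pixels (attenuation from
pixels with degenerate, heavily tied permutation distributions). The
package reproduces the rule as published rather than halving α.

### Cluster correction conventions

Two conventions needed pinning down at reduced iteration counts:

- **Self-inclusion.** Retained cluster-null maps are scored against the
  full resampled set. Counting a map's own value ("leave-self-in",
  p = c/N) makes the null maps' pixel test *stricter* than the true
  map's add-one test at small N (at N = 500 and α = 0.01: at most 3
  others may exceed a null-map pixel vs 4 for the true map), which
  deflates the null cluster sizes and inflated the measured family-wise
  error to ≈ 0.14 in a 100-run battery. The default is therefore
  leave-self-out (p against the other N − 1 maps), which makes the two
  tests symmetric; the conventions coincide as N grows.
- **Survival rule.** The literal "top 5% nearest-rank" recipe
  (threshold at the ⌈0.95K⌉-th smallest null max size, survive if ≥)
  has inherent type-I probability ⌈... ⌉ discreteness of
  (K + 1 − ⌈0.95K⌉)/(K + 1) — 5.6% at K = 125 — plus integer-tie
  inflation; a pseudo-true diagnostic (an extra exchangeable resampled
  map scored as if observed) measured 8.3% survival. The default is
  therefore the standard exact max-statistic rule: a cluster of size s
  survives iff (1 + #{null max ≥ s})/(K + 1) ≤ 0.05, which guarantees
  family-wise validity at any K (measured FWER 0.037, CI 0.021–0.064,
  over 300 null runs). The nearest-rank recipe remains available as
  `cluster_rule="nearest_rank"`.

Other declared choices: 8-connectivity for clusters (4 available);
positive and negative suprathreshold pixels are labelled separately so
clusters are sign-coherent; the cluster-null subset is the first K of
the N iterations (they are i.i.d., so any subset is equivalent);
the permutation stream is consumed block-wise, making `block_size` part
of the reproducibility contract recorded in run manifests.

## Calibration problem sizes

The calibration and power batteries use 20 participants, 8 trials per
contrasted condition, 16 faces, fixations 2–5, a 0.1°/px grid, and 500
permutations with 125 cluster-null maps — about one second per run, so
batteries of hundreds of independent runs are routine. The acceptance
script averages 300 null runs; the test suite uses 100 with a binomial
confidence-interval check. Power: the planted 1.5° shift is detected
(surviving cluster of the correct sign on the opposite side of the
face) in 100% of 50 runs at these sizes.

## Known limitations

- Translation-only alignment cannot absorb inter-face scale or rotation
  differences; faces are assumed pre-scaled (as when stimuli are
  normalized to a common forehead width).
- The AOI tie-priority order (eyes > nose > mouth) is a convention;
  boundary fixations are rare with continuous coordinates but the
  choice is observable in AOI frequency tables.
- Trials with fewer than five fixations are retained with their
  available fixations (a strict mode drops them); with very short
  trials the per-ordinal strata become unbalanced, which the stratified
  permutation handles but which reduces power at late ordinals.
- d′ uses the 1/(2N) extreme-rate correction; with very few trials per
  cell the estimate is biased toward zero.
- The permutation test assumes exchangeability of locations across
  trials within a stratum; serial dependence between trials (fatigue,
  learning) is not modelled by the generator and would not be detected
  by these calibrations.
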