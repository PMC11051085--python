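# Methods

This note records the mathematical model, the parameters and their
defaults, the synthetic-cohort design, and the numerical choices made in
`gaitmatch`.

## 1. Kinematic model

### Canonical skeleton

All pipelines reduce input landmarks to a canonical 16-keypoint
skeleton: left/right shoulder, elbow, wrist, hip, knee, ankle, heel and
foot tip. MediaPipe-33 input is subset to these 16; COCO-18 input (no
heel / foot-tip landmarks) maps to the 12-keypoint subset. Cleaning
policy: frames whose required joints fall below the visibility threshold
(default 0.5) are dropped, never interpolated; if more than a fraction
(default 0.5) of frames would drop, the sequence is rejected as degraded.

### Joint angles

Each joint angle is the interior angle at a *vertex* joint between two
adjacent segments. For landmark triple (proximal `P`, vertex `V`,
distal `D`) the triangle legs are the Euclidean distances

    a = |V − P|,   b = |V − D|,   c = |P − D|

and the vertex angle follows from the law of cosines

    θ = arccos( (a² + b² − c²) / (2ab) ),

reported in degrees, always in [0, 180]. The arccos argument is clamped
to [−1, 1] to absorb floating-point excursions on near-collinear
triples; frames with a = 0 or b = 0 (vertex coinciding with an endpoint)
are dropped with a warning. Angles built this way are invariant under
rigid motion and uniform scaling of the landmarks (verified in tests to
1e−9 degrees over random similarity transforms), which is what makes
them usable across camera views.

The whole-body set has ten angles, in fixed column order: LElbow,
RElbow, LHip, RHip, LKnee, RKnee, LAnkleFront, RAnkleFront, LAnkleBack,
RAnkleBack (ankle front = knee–ankle–foot-tip, ankle back =
knee–ankle–heel). COCO-18 sources support the first six. Body parts:
*upper* = the two elbow angles, *lower* = the remaining eight (four on
COCO), *whole* = all.

## 2. Features

### Raw angle series

The T × J matrix of per-frame angles, J ∈ {10, 8, 2} by body part.

### Spearman rank-correlation matrix

Each column is replaced by ascending fractional ranks: the minimum gets
rank 1, and a run of m equal values occupying integer ranks r…r+m−1 all
receive their mean (r + r+m−1)/2 (so a tied pair at sorted positions 3
and 4 of five values receives 3.5 — the worked example measured by
`scripts/acceptance.py`). The correlation between two columns is the
Pearson correlation of the rank vectors in expectation form,

    ρ = (E[XY] − E[X]E[Y]) / ( √(E[X²]−E[X]²) · √(E[Y²]−E[Y]²) ),

computed over the full sequence, mirrored to an exactly symmetric J × J
matrix, and clipped to [−1, 1] against round-off. A zero-variance
(constant) column makes the denominator vanish; such pairs are assigned
0 ("no monotone relationship") with a warning rather than NaN, so
downstream distances stay finite.

### Distance

Dependent multi-dimensional dynamic time warping (DTW): one warping path
shared by all J dimensions, local cost = Euclidean distance between
J-vectors, symmetric three-way step pattern (match, insert, delete), no
window, no path-length normalization. The distance is the minimum
accumulated local cost over monotone paths from (0,0) to (T₁−1, T₂−1);
the dynamic program is verified in tests against brute-force enumeration
of all warping paths (> 3000 pairs). Backtracking prefers the diagonal
step on ties. For correlation features, the J rows of the J × J matrix
are treated as the sequence, so matrices of equal J still produce a
warping-based comparison of their row profiles. The inner dynamic
program is JIT-compiled with numba; the first call in a process pays the
compilation cost (~1 s).

## 3. Matching protocol

Identical-view protocol: a probe's sequence from view v is compared only
to gallery sequences from view v (a `view_map` permits cross-view
pairing but is not the default). Per view, the predicted identity is the
DTW argmin (ties → smallest label). The final identity is the majority
vote over views; vote ties are broken by smallest summed distance across
views, then by smallest label.

Accuracies: *without voting* = correct (probe, view) decisions / all
(probe, view) pairs; *with voting* = correctly voted probes / probes.
Probes absent from the gallery are flagged (`in_gallery = false`) and
counted incorrect.

## 4. Synthetic cohort generator

Standard multi-view gait corpora are access-restricted, so experiments
run on a seeded generator that emulates the statistical structure the
pipeline assumes — not gait biomechanics in detail.

### Signal model

Each subject's angle j follows a sinusoid

    θ_j(t) = mean_j + amp_j · sin(2π f t + φ_j) + ε,   ε ~ N(0, σ_view²),

clipped to [0, 180]°, with a subject-specific stride frequency f and
per-angle means, amplitudes and phase lags around physiological
baselines (elbow 155° ± 8°, hip 155° ± 10°, knee 140° ± 22°, ankle
front 115° ± 12°, ankle back 95° ± 10°; lags 0–1.9 rad through the
stride). Right-side leg angles run in antiphase (+π), as in normal gait.
A *reference* bout starts at phase 0; a *target* bout of the same
subject draws a uniform random integer-frame time shift (an independent,
unsynchronized second walk). The view effect is additive i.i.d. angle
noise per (subject, view, role); no camera projection is modelled.

Defaults (`CohortConfig`): 20 subjects, 11 views labelled 0°–180° in 18°
steps, T = 100 frames, `mean_spread` 8°, `amplitude_scale` (0.7, 1.3),
`frequency_range` (0.03, 0.06) cycles/frame (stride period 17–33 frames,
≈ 0.9–1.8 Hz at 30 fps), `phase_spread` 0.5 rad, `view_noise_sd` 0. The
calibrated moderate operating point `MODERATE_VIEW_NOISE_SD = 19.0°`
yields ≈ 0.60 single-view accuracy (10-seed mean) on the default cohort,
the regime where cross-view voting has room to help.

### Design for noiseless identifiability

The generator is required to satisfy: as σ_view → 0, matching accuracy →
1.0 for every feature kind and body part. With fully independent
parameter draws this fails occasionally — the upper-body features see
only the two elbow columns, and with 20 subjects two sets of
independently drawn elbow parameters sometimes nearly coincide. The
generator is therefore *designed* identifiable (validated across nine
cohort seeds, not tuned to any one):

* **Whole-cycle frequencies.** f = k/T with integer cycle count k in the
  configured band, preferring k coprime with T. Sampling whole cycles
  makes a bout's value multiset invariant to the integer-frame target
  shift, so rank statistics are exactly bout-invariant; coprime k visits
  T distinct stride phases, giving the rank-correlation map its finest
  resolution (no plateaus that would duplicate correlations across
  subjects).
* **Stratified elbow correlation.** The left–right elbow phase gap is
  set by numerically inverting the (frequency-specific) gap → Spearman
  map so that the cohort's L–R elbow correlations are evenly spaced in
  [−0.92, 0.92] and randomly assigned. Every subject pair is then
  separated by ≥ 1.84/n in the 2 × 2 upper-body correlation feature.
* **Grid-assigned elbow means.** The (LElbow, RElbow) mean offsets come
  from a space-filling grid over the ±`mean_spread` square (random
  subset, random assignment), guaranteeing every pair ≈ 4° or more of
  elbow-posture separation — a difference time warping cannot remove,
  which keeps the two-column angle-DTW feature discriminative against
  the unavoidable alignment cost of a phase-rotated periodic bout.

All other parameters (leg means, amplitudes, leg phase lags, the
noise streams) are independent uniform/normal draws. Randomness is
organized as `SeedSequence` spawn-key substreams per (subject, view,
role), so datasets are bit-identical for identical (config, seed) and
reference/target noise is independent.

### Landmark embedding

A planar kinematic chain (fixed hip/shoulder roots, constant segment
lengths) articulates the canonical-16 landmarks so every generated
interior angle is realized exactly; law-of-cosines extraction recovers
the generating angles to ≤ 1e−6° in the jitter-free case, which
exercises the pose-reading and angle-extraction stages end to end.
Optional Gaussian landmark jitter (metres) degrades the recovery
monotonically.

### What the generator does not model

Camera projection and view-dependent self-occlusion (views differ only
by noise realization), stride-to-stride variability within a bout,
transient gait events (turns, stops), soft-tissue/marker artifacts, and
pose-estimator failure modes beyond i.i.d. jitter.

## 5. Numerical choices

* Law-of-cosines argument clamped to [−1, 1]; degenerate triples (zero
  leg) drop the frame rather than emitting NaN.
* Tied ranking via a stable argsort with run-averaging; conserves total
  rank mass T(T+1)/2 exactly.
* Correlation in expectation form on ranks, clipped to [−1, 1];
  zero-variance columns map to 0 with a warning.
* DTW in float64; accumulation by dynamic program (numba-JIT), distances
  are exact path sums (no normalization), diagonal preferred on ties.
* CSV writers emit `repr(float(x))` so round-trips are bit-exact.
* All stochastic code takes explicit integer seeds; cohort generation
  derives per-(subject, view, role) substreams from a root
  `SeedSequence`, so adding views or subjects does not perturb existing
  streams.

## 6. Verification problem sizes

Chosen to give dense coverage within a minutes-scale test budget: DTW
dynamic program vs exhaustive enumeration on all 1521 pairs of sequences
of length ≤ 3 over {0, 1, 2} plus 1500 seeded random pairs of lengths
4–6 (enumeration is exponential in length, so longer sequences are
sampled rather than exhausted); Spearman vs the tie-corrected reference
implementation on 1000 seeded pairs with forced ties; rigid-invariance
of angles on 1000 random similarity transforms; the noiseless-recovery
experiment on the full default cohort (20 subjects × 11 views, both
feature kinds × three body parts); vote-dominance as a one-sided t test
over 50 seeded cohorts at the moderate-noise operating point.

## 7. Limitations

* The identical-view protocol assumes the probe's view label is known
  and present in the gallery.
* DTW distances are unnormalized path sums; comparing distances across
  sequence lengths mixes scale with dissimilarity (matching only ever
  compares equal-length features, so ranking is unaffected).
* The correlation feature collapses temporal dynamics entirely; two
  different gaits with identical inter-joint rank coordination are
  indistinguishable to it.
* Synthetic results demonstrate pipeline correctness and the value of
  voting under the stated noise model; they are not evidence about
  real-world gait-recognition accuracy.
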