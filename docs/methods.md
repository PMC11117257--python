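# Methods

This note documents the models, parameters and numerical choices behind
`pentrack`, and what the synthetic validation does and does not show
about real pen video.

## Tracking model

**State and motion.** Each identity carries an 8-dimensional Kalman
state `(cx, cy, a, h, v_cx, v_cy, v_a, v_h)` — box center, aspect ratio
`w/h`, height, and their velocities — with constant-velocity dynamics.
Process and measurement standard deviations scale with the box height
(position weight `h/20`, velocity weight `h/160`), the convention of the
SORT/DeepSORT/StrongSORT family, so the filter adapts to animal size
without extra tuning.  Camera-motion compensation is a pluggable
per-frame affine hook applied to predicted positions; it defaults to
identity because the intended deployment is a fixed overhead camera and
the package never touches pixel data from which a registration could be
estimated.

**Confidence-adaptive update.** The measurement update scales the noise
covariance with the detector confidence `c`: `R̃ = (1 − c)·R`.  A
confident detection (c → 1) overwrites the predicted position; a
doubtful one barely perturbs it.  Closed forms used as tests: at `c = 1`
the posterior measurement projection equals the measurement to 1e−8; at
`c = 0` the update is the textbook update with `R` to 1e−10; the weight
on the measurement is non-decreasing in `c`.

**Appearance.** Tracks keep an exponential moving average of the
unit-norm embeddings they absorb, `e_t = α e_{t−1} + (1 − α) f_t` with
α = 0.9 (config-exposed).  The raw accumulator follows this recursion
exactly — after `k` constant-input updates it equals
`α^k e_0 + (1 − α) Σ_{j<k} α^j f` — while the matching template is its
L2 normalization, which keeps the cosine cost `1 − r·e` inside [0, 2].
Detections without embeddings (a detector with no re-ID head) get the
neutral cost 1, degrading gracefully to motion-driven matching.

**Association.** The per-frame cost is `C = λ A_α + (1 − λ) A_m` with
λ = 0.98 (appearance-dominant), `A_α` the cosine distances and `A_m`
the squared Mahalanobis distance of the 4-D box measurement under the
predicted state, divided by the gate so it is ≈ [0, 1] inside.  Pairs
are inadmissible beyond the Mahalanobis gate (χ² 0.95 quantile at 4
dof, 9.4877) or the appearance gate (cosine distance 0.4).  One global
Hungarian assignment (maximum cardinality over admissible pairs, then
minimum cost — `scipy.optimize.linear_sum_assignment` with a large
constant on inadmissible entries) resolves the frame; there is no
matching cascade.  The motion term is a Mahalanobis, not cosine,
quantity: that is the only reading of the combined-cost construction
consistent with the gating description, and it is the established
StrongSORT form.

**Closed-pen lifecycle.** Tracks are never deleted; an unmatched track
becomes `occluded` and keeps accumulating prediction uncertainty, which
*widens* its effective gate (the innovation covariance grows roughly
like t³ in position, so the Mahalanobis distance of the true
reappearance stays small even after hundreds of frames).  New tracks are
created from unmatched detections only while the track count is below
`n_max`, highest-confidence first; surplus detections at the cap are
dropped with a logged warning.  If unmatched detections remain at the
cap while occluded tracks exist, both admissibility gates are multiplied
by 1.5 and the leftover sub-problem is re-solved, up to 3 times.  New
tracks are active immediately: with a hard cap and no deletion, a
tentative confirmation period would only delay convergence to the fixed
population.  A DeepSORT-style reference lifecycle (tentative
initialization over 3 frames, deletion after 30 unmatched frames, no
cap) is included solely as a comparison baseline for identity-stability
experiments.

## Offline corrections (off by default)

Both corrections are optional because the online tracker alone is the
deployment configuration; they trade runtime for completeness.

**GSI.** Per identity, each of `(cx, cy, w, h)` is regressed on the
frame index with a Gaussian process (RBF kernel, length scale 10 frames
held fixed; white-noise level fitted by marginal likelihood;
`normalize_y`).  Missing frames inside gaps up to `max_gap` (default 3
s × fps) are filled from the posterior mean and observed frames are
replaced by it.  Trajectories longer than ~350 observations are fitted
in overlapping 300-observation windows (25 observations of shared
context; each window's interior is kept), keeping the cubic GP cost
linear in track length; with a 10-frame correlation length the windows
are statistically independent far from their joins.  The operation is
idempotent to < 0.1 px and recovers a 10-frame gap in a noiseless
linear track to < 1 px RMSE.

**Tracklet linking.** A candidate (predecessor, successor) pair is
summarized by the nearest N = 30 frames of `(frame, x, y)` on each side
of the junction, zero-padded when shorter.  The scorer extracts
temporal-difference features along the time axis (mean and spread of
per-frame velocity on each side), fuses them with the junction deltas
(frame gap, spatial offset, forward/backward extrapolation residuals),
and classifies with a small MLP (two hidden layers, 32/16; lbfgs;
deterministic per seed) emitting a confidence in [0, 1].  It is trained
on simulator-generated cut pairs: positives are one ground-truth
trajectory cut at a random frame with a 1–30-frame gap, negatives pair
the tail of one identity with the head of another; a quarter of the
pairs is held out and the held-out accuracy is stored on the model
(≥ 0.9 on default scenarios).  Association applies spatiotemporal
constraints (gap ≤ 30 frames, offset ≤ 75 px, confidence ≥ 0.9), then a
linear assignment on `1 − confidence`; accepted links relabel the
successor with the predecessor's id, so the identity count never grows.

## Metrics

Per-frame correspondence is one-to-one maximum-IoU matching at IoU ≥
0.5 (configurable).  MOTA is `1 − (FN + FP + IDSW)/Σ gt` as a
percentage; an identity switch is a change in the predicted id matched
to a ground-truth identity relative to its most recent match.  IDF1
uses the optimal global bipartite assignment between gt and predicted
identities.  HOTA follows the standard definition — per localization
threshold α ∈ {0.05, …, 0.95}, `sqrt(Σ_c A(c) / (TP + FN + FP))`,
averaged over α — including the square root.  MOTP is reported in the
overlap convention (mean match IoU as a percentage), because a
"precision ≈ 90 %" reading is only meaningful as a similarity; the
distance forms (mean 1 − IoU, mean center distance in px) are returned
alongside.  All metrics are invariant to global relabeling of predicted
ids; each is cross-checked in the tests against an independently coded
loop/enumeration oracle.

## Zone-occupancy analysis

The default pen partition is defecating (490,200)–(720,975), resting
(720,200)–(1480,975) and eating (1480,200)–(1580,975) in pixels, with
everything else `irrelevant`.  Rectangles are half-open (`left ≤ x <
right`), so shared boundaries belong to exactly one zone and
classification is total.  Because a feeding animal's box center trails
its head by about 230 px, any center with `x ≥ 1350` (the trough edge
1580 minus the head offset) inside the eating rectangle's y-range
counts as eating; the fixed-boundary rule is used rather than a
per-animal orientation correction, which box-only data cannot support.

Trajectories are gap-filled by linear interpolation (the gaps this
addresses are a few frames of detector dropout, where linear is the
minimal assumption), classified per frame by box center, grouped into
seconds of `round(fps)` frames, and labelled by majority vote — ties go
to the previous second's label (first second: earliest frame's zone) for
temporal coherence.  Stay-time tables therefore conserve time: per
identity, zone-seconds sum to the analyzed duration.  Relative errors
against a reference table are `|obs − ref|/ref × 100` per cell (0 when
both are 0), row means per identity, column means per zone, and the
overall error is the mean of the per-identity means.  On the bundled
24 h manual-vs-tracked comparison this pipeline reproduces the published
error analysis; two printed values (one cell and one row mean) differ by
one unit in the second decimal because the published aggregates were
computed from already-rounded cells, and the tests compare those at the
printed last-digit precision.

## Simulator

The generator stands in for barn video and encodes the study
conditions: a fixed population confined to a rectangular pen (every
animal present in every ground-truth frame), per-animal
Ornstein–Uhlenbeck velocities (`dv = −0.5·v·dt + σ_v √dt·dW`, tuned to
a ~35 px/s per-component speed scale) with reflecting walls, and
per-animal body rectangles (~130 × 80 px).  The detection channel
applies: occlusion episodes (Poisson starts at 2 events per
animal-minute; duration uniform on 25–250 frames; detections dropped
for the whole episode), a 1 % baseline miss rate, Gaussian box jitter
(sd 1.5 px on corners, 0.75 px on sizes), and confidence
`clip(0.95 − 0.6·overlap, 0.3, 1)` where `overlap` is the largest
fraction of the animal's box covered by another.  The false-positive
rate defaults to 0 — the intended detector class operates above 99 %
precision on this task — but is config-exposed.  Embeddings are
`normalize(p_id + σ_e·N(0, I))` in 128 dimensions with prototypes
uniform on the unit sphere; σ_e = 0.05 keeps the within-identity cosine
distance (≈ 0.13 in expectation) well inside the 0.4 appearance gate
while between-identity distances stay near 1, emulating a
well-separated trained re-ID extractor.

What the simulator does **not** model: pixel appearance (lighting,
motion blur), correlated occlusion geometry (the occluder and occluded
are independent here), social behavior, detector-specific error
structure, and camera motion.  Passing the synthetic suite therefore
demonstrates the *association logic* — identity preservation through
long occlusions under the closed-pen constraints — not detector
robustness on real video.

## Problem sizes and determinism

The identity-stability experiments use ten replicates of 10,000 frames
(4 animals, 25 fps, ≈ 45 occlusion episodes per replicate), a scale at
which every occlusion-recovery pathway (gate relaxation, long-occlusion
re-matching, cap pressure) is exercised thousands of times while a full
run stays in the minutes range on one CPU.  Every stochastic component
(simulator, training pair generation, classifier initialization) is
driven by an explicit seed; identical seeds give byte-identical
scenarios and identical tracker output.

## Known limitations

* The id cap makes the tracker wrong by construction if the true
  population changes (death, removal, regrouping); it targets static
  pens between interventions.
* A surplus of confident detections at the cap (e.g. persistent false
  positives in an already-full pen) is dropped, not arbitrated.
* The tracklet linker's constraints (gap ≤ 30 frames) mean it cannot
  heal fragmentations longer than ~1 s at 25 fps; in the closed-pen
  lifecycle such fragments do not arise, which is why both corrections
  are off by default.
* MOTP's overlap convention and the IoU-0.5 matching threshold are
  conventions; numbers are comparable across runs of this package but
  only approximately across tools with different conventions.
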