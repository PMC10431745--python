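# Methods

This note documents the models, procedures and numerical choices behind
`megscenes`, in the order data flows through the pipeline.

## Study design emulated by the generator

Two experiments per subject, 28 subjects by default:

* **Pattern localizer** (intact scenes): indoor/outdoor × old/new,
  30 trials per condition per run, 12 one-back target repeats per run,
  4 runs — 132 trials/run.  Each of the 30 exemplars per condition
  appears once per run, so exemplar averaging yields 120 unique patterns
  (30 per condition × category).
* **Main experiment** (degraded stimuli): indoor/outdoor ×
  scene / scene-with-object / object, 30 trials per condition per run,
  18 one-backs, 4 runs — 198 trials/run.  The 30 scenes per category
  are split into two fixed sets of 15: one set appears with its
  foreground object, the other alone, swapped on odd subject indices so
  the split is counterbalanced across subjects.  Objects-alone carry the
  foreground objects of the scene-alone set, so no pixel content repeats
  between scene-with-object and object-alone within a subject (the
  object-alone assignment is a convention; either set satisfies the
  design arithmetic).  With 30 trials over 15 exemplars, every exemplar
  repeats twice per run; averaging yields 90 unique patterns (15 per
  condition × category).

One-back rows duplicate the immediately preceding trial's image and are
discarded before analysis.  Inter-trial intervals (uniform 1200–1600 ms),
fixation (500 ms) and stimulus duration (83 ms) are carried as metadata
only: epochs are stimulus-locked 0–500 ms windows on a 10-ms grid
(50 bins), generated natively at that resolution.  An optional
block-mean decimation stage (`decimate_to_grid`) maps user-supplied
1 kHz epochs onto the grid; block means rather than filter-then-decimate
because the choice is deterministic and testable, and the analysis never
touches the high-rate signal.

## Sensor layout

102 magnetometers on concentric rings of a flattened helmet (arbitrary
units, +y anterior), with 204 co-located planar gradiometers carried as
metadata only.  The designated decoding scope is a left-posterior set of
24 magnetometers chosen by a deterministic coordinate rule: among
channels with x < 0 and y < 0, the 24 most posterior, ties broken by
channel id.  (Whether the original selection was by vendor grouping or
coordinates is unknowable from the outside; a coordinate rule is the
reproducible choice.)

## Signal model

For trial *i*, channel *c*, time *t*:

```
data[i,c,t] = sign(category_i) · Σ_k a_k(condition_i) · w_k[c] · g_k(t)
              + e(exemplar_i) · u[c] + noise[i,c,t]
```

* `w_k` — subject-specific unit-norm spatial pattern, restricted to a
  scope (default: the left-posterior set).  Patterns are drawn per
  subject and shared between experiments, which is what makes
  localizer→main transfer possible.  A component may reuse another
  component's pattern (`pattern_of`): a facilitation that *strengthens*
  an existing representation must ride on the same pattern, otherwise a
  classifier trained where only the base component is present could not
  read it.
* `g_k` — temporal envelope, Gaussian or Ricker (Mexican hat).  The
  default components use Ricker envelopes because they have zero
  temporal mean: per-epoch demeaning (below) then leaves the planted
  signal intact.  A positive-only bump would leak an inverted copy of
  its mean into every bin after demeaning, mis-orienting classifiers at
  signal-poor latencies — an artifact of demeaning an all-signal window,
  not of the decoder.  Physically, evoked transients recorded through a
  0.1-Hz online high-pass are approximately zero-mean and biphasic.
* `e` — per-exemplar offset, N(0, exemplar_sd), identical across
  repetitions of an exemplar (so it survives exemplar averaging —
  exemplar identity is a real, repeatable source of variance).
* noise — unit marginal variance, exponential spatial correlation over
  sensor distance (length 0.3 layout units) and AR(1) temporal
  structure (ρ = 0.3), scaled by `noise_sd` (default 1).

Default planted scenario (the generator's study conditions):

| component | envelope | center | width | amplitudes |
|---|---|---|---|---|
| category_response | Ricker | 205 ms | 55 ms | old/new 0.55; degraded conditions 0 |
| object_based_boost | Ricker | 325 ms | 13 ms | scene_with_object −0.45 (pattern of category_response); others 0 |

The category response makes intact scenes decodable along the central
band of the matrix diagonal, peaking ≈ 200 ms and falling to chance at
the epoch edges; its inverted late phase spans ≈ 270–370 ms.  The boost
amplifies that late phase (hence the negative amplitude) for
scene-with-object only — the facilitation the inference stack should
recover at 300–350 ms.  Degraded scenes alone and objects alone carry no
category signal, so both paired contrasts isolate the boost; making
scene-alone weakly decodable (as real data can be) is a one-line config
change but would add a genuine early difference to the vs-object
contrast.  Amplitudes are scaled so group-mean peak accuracies sit in
the range typical of sensor-space MEG category decoding (intact ≈ 0.9
at peak, scene-with-object ≈ 0.7) rather than at ceiling.

Seeds: one master seed; `numpy` `SeedSequence(master, spawn_key=…)`
counters give independent streams — `(subject, 0)` for subject-level
patterns, `(subject, 1+experiment)` for per-experiment noise and
offsets, `(subject, 10+experiment)` for trial order.  Identical config
and seed give bit-identical data.

## Preprocessing

Fixed order: drop one-backs → detrend → (decimate) → average exemplar
repetitions → temporal smoothing → channel selection.

* Detrending removes the best-fit polynomial (order 1 by default — the
  plausible reading of "demean + detrend"; order 0 available) per trial
  per channel.  Per-epoch application is a documented choice; applying
  it per continuous recording is not possible for epoched input.
* Smoothing is a boxcar of radius 2 bins (±20 ms) with truncated
  (shrinking) windows at the epoch edges — no data is invented outside
  0–500 ms.
* Channel selection restricts to the left-posterior 24 for the matrix
  analyses; the searchlight keeps all 102 magnetometers.

## Decoding

Two-class LDA with ridge ("shrinkage") regularization: pooled
within-class covariance with denominator n − 2 (unbiased for two
classes; the convention is documented because n is small), plus
0.01 · mean(diag Σ) on the diagonal — strictly positive by config, so
training succeeds on rank-deficient pattern sets.  Equal class priors
(every train/test set here is balanced); ties on the decision boundary
go deterministically to class 0 (a measure-zero event on continuous
data).  Accuracy is raw proportion correct, which equals balanced
accuracy for these balanced sets.

The scheme is pure transfer: within-localizer decoding trains on the 60
old-scene patterns and tests on the 60 new-scene patterns; cross-
decoding trains on all 120 localizer patterns and tests on each main
condition's 30.  Training at each of the 50 bins and testing at all 50
gives the 50 × 50 matrix; the diagonal time course averages the square
±2-bin window around each diagonal cell (truncated at edges).

## Inference

One-sample t against h0 (0.5 for accuracy, 0 for paired differences),
sd denominator n − 1.  Zero-variance cells get a ±1e12 sentinel, clamped
to ±100 before TFCE so the threshold ladder stays finite; this arises
only in degenerate synthetic inputs.

TFCE uses the discrete ladder h = dh, 2dh, … ≤ t(e) with dh = 0.1 on the
t scale, extent exponent E = 0.5 and height exponent H = 2 (the
field-standard defaults of the enhancement).  Implementation note:
thresholds between two consecutive distinct map values share the same
supra-threshold set, so connected components are computed once per
distinct value and per-step weights accumulated analytically — the
result is exactly the naive per-threshold loop, at a fraction of the
cost (verified against a brute-force BFS oracle in the tests).
Connectivity: adjacent bins for 1-D courses, 4-connectivity for
time × time grids, and the symmetrized mutual-neighborhood channel graph
for sensor maps.

The permutation null flips the sign of each subject's whole centered map
with probability ½ (1,000 permutations by default; the examples and
tests use 250 where runtime matters, which still resolves p = 1/251)
and records the maximum TFCE within the analysis mask.  Corrected
p = (1 + #{perm max ≥ observed}) / (1 + n_perm), so the smallest
attainable p is 1/(n_perm+1).  Sign assignments are keyed to a canonical
ordering of the subject maps (rows sorted by their value multiset), so
p-values are exactly invariant to subject ordering and to channel
relabelling.  One-sided positive tests by default (above-chance decoding
and directional facilitation); a two-sided option applies TFCE to |t|
and restores the sign.

Masking: intact-scene (old→new) decoding is tested over the full 50 × 50
grid; its significant cells form the temporal mask for all cross-
decoding tests, and the mask's diagonal gates the paired time-course
contrasts (a convention — the diagonal of the matrix mask, rather than a
separately computed diagonal mask).  Elements outside a mask have
undefined p and are never significant; an empty mask warns and returns
nothing significant.

## Searchlight

Neighborhood of a channel = the channel plus its 14 nearest
magnetometers by layout distance (ties by channel id; the center counts
toward the 15, the standard convention).  Decoding runs per neighborhood
per 10-ms bin on the diagonal only, then accuracies are averaged into
ten 50-ms clusters (decode-then-average, the natural reading of
averaging *accuracies* into clusters).  Facilitation is tested per
cluster independently — paired sign-flip TFCE over channels with its own
max-statistic null — with no additional correction across the ten
clusters, mirroring the per-cluster testing the procedure defines.
Consequence worth knowing: with ten independent 0.05-level family-wise
tests, a stray significant cluster appears in roughly a third of null
studies; the planted effect is identified as the dominant cluster, not
by assuming the others are empty.

## Orchestration and outputs

`run_full_analysis` composes the stages (localizer inference first, its
mask gating everything downstream; paired contrasts for
scene-with-object vs scene-alone and vs object-alone; searchlight last)
with subject-level parallelism via joblib — reductions are
order-insensitive, so results do not depend on worker count.  CSV/JSON
are the canonical outputs (group matrices with significance flags,
per-subject diagonal courses, tidy searchlight maps, a results summary
with the master seed and a config content-hash); figures are
conveniences rendered from the same arrays.  Rerunning into a directory
whose manifest carries the same config hash is a no-op.  Configuration
is a single YAML document validated strictly: unknown keys and invariant
violations are rejected with their field paths.

## Problem sizes used in the checked examples

The test suite runs the full 28-subject study once with 250 permutations
(the latency-recovery check), a 10-subject zero-signal study (chance
calibration, also what `scripts/acceptance.py` recomputes), and a
200-replicate × 250-permutation null simulation on 20-bin courses with
10 subjects (family-wise error calibration: the observed FWER must stay
within the binomial envelope of the nominal 0.05).  These sizes were
chosen to estimate each quantity to the precision its assertion needs.

## What passing tests do and do not show

The generator produces linear, stationary, Gaussian signals with a known
shared spatial pattern and exactly balanced designs.  Real MEG adds
head-motion and environmental artifacts, non-Gaussian and non-stationary
noise, between-subject latency jitter, imperfectly repeatable exemplar
responses and unbalanced effective trial counts after artifact
rejection.  Passing tests therefore validate the *pipeline* — its
bookkeeping, estimators, error control and ability to recover a planted
spatiotemporal effect — not the empirical claims of any particular
recorded dataset.  Known limitations: no artifact rejection or filtering
stages (by design), no gradiometer analysis, no source localization, and
the per-epoch detrend convention discussed above.
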