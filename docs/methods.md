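# Methods

This note documents the models, estimators and numerical conventions behind
`ovipost`, the choices made where the design was genuinely open, and what
the synthetic-data benchmarks do and do not establish about real data.

## Ethogram representation

An ethogram is a frame × 7 boolean activity matrix at the video frame rate
(default 20 Hz), frames 0-based, bouts half-open `[start, end)`, times
reported as `frame / fps` seconds. The representation is deliberately
multi-label: an abdominal bend is maintained throughout burrowing, egg
expulsion and detachment, so a single-label stream cannot encode the
deposition phase. The one structural exclusion enforced at validation is
walking during burrowing. Completed egg expulsion (`egg_out`) is stored
natively as a single frame — the first frame at which the egg reaches its
maximum depth — and is widened to three frames only inside the agreement
module, matching how point-like labels are treated when annotations are
compared.

Single-stream consumers (the transition analysis) derive an onset sequence
rather than flattening the matrix. Onsets that coincide on a frame are
ordered by a fixed priority (`egg_out > burrow > bend > detach > groom >
pe > walk`); such ties are rare and the priority is part of the contract
rather than a tunable.

## Start-to-start transitions

The unit of analysis is the behavior onset; consecutive onset pairs within
an event are the transitions. Three scoring conventions are applied when
extracting onsets: proboscis extensions closer than 0.5 mm to the last
counted extension are not re-counted (requires the optional location
track; without one the filter is skipped and the skip is recorded in the
sequence provenance); proboscis extensions beginning while another behavior
is active are omitted; and a sustained bend contributes one onset even when
burrowing aborts and restarts inside it — the last property falls out of
the bout representation, in which one bend bout is one onset.

Counts are pooled across events and flies before row normalization, giving
one population matrix; the pre/post split anchors at the expulsion onset,
which terminates the pre-phase sequence and opens the post-phase one.
Whether to pool or to average per-fly matrices was an open choice; pooling
is the default because the per-event sequences are short, and per-fly
matrices remain available by calling the estimator per fly.

Significance is a one-sided permutation test. The shuffle unit is the
label order within each sequence (phase-respecting), which preserves every
event's behavioral repertoire and sequence length under the null; the
statistic is the cell's row-normalized probability, and
`p = (1 + #{permuted ≥ observed}) / (1 + n_perm)` — the add-one estimator,
so p is never zero and the test is valid at finite `n_perm`. Defaults:
10,000 shuffles, α = 0.001, and a probability floor of 0.04 below which a
transition is never called significant regardless of p. The permutation
loop shuffles all sequences simultaneously with a segment-wise random
re-ordering (`lexsort` over per-element random keys), so 999 shuffles of a
cohort cost milliseconds.

## Burrow episodes, eggs and the photostimulation rule

A burrowing episode is one contiguous burrow bout; annotated cycle frames
are partitioned among episodes and an episode expels iff the expulsion
frame lies within its closed interval (expulsion closes the episode, so the
boundary frame belongs to it). The cycle/duration association is summarized
by the Pearson r over all episodes; the estimator is Pearson because the
relationship is linear by mechanism (cycles recur at a roughly fixed rate),
and the choice is recorded here because the summary statistic's family was
not otherwise pinned down.

Egg records carry a depth score in {0, ½, 1} (fully buried / partial /
surface), a location (substrate vs wall) and a mode (burrowed vs dropped).
"Dropped" is operationalized, when derived from an ethogram rather than
scored directly, as an expulsion with no burrow activity in the preceding
5 s (configurable). Per-fly summaries apply per-metric minimum egg counts
(defaults: 1 for depth, 3 for wall fraction, 2 for drop fraction), emitting
NaN rather than silently averaging under-sampled flies.

The post-expulsion classifier uses the end of the expelling episode as the
burrow-stop time — a proxy for the separately-annotated instant of
ovipositor detachment, recorded here as a convention. A trial *advances*
if no burrow onset occurs within the 65-s reset gap after the expelling
episode, and *reverts* otherwise, with the reset anchored at the onset of
the last burrowing episode that precedes a 65-s burrow-free window (the end
of the recording counts as burrow-free). A burrow stop exactly at light
offset is binned as stopped-at-offset. The expelled-after-stimulation flag
is true iff the egg emerged no later than 4 s after the last pulse offset.

## Pose features

The 17 features are, in fixed column order: `vel` — scutellum displacement
across a 10-frame (500 ms) lag divided by the lag, in px/s (conversion to
mm/s via `px_per_mm` is available; the matrix stores px/s); `pe` —
per-frame displacement of the proboscis tip relative to the ocellus;
`ba` — the signed angle between the A2→A6 ventral stripe line and the
ocellus→scutellum body axis, z-scored per recording; `velba` — the frame
difference of the un-normalized angle, then z-scored; `T1`–`T3` — per-frame
leg-joint displacements; `Pegg` — the pose model's egg-emergence
confidence, passed through; `w1ovi`/`w2ovi` — mean Morlet magnitudes over
the 0.8–1.3 and 1.3–2.3 Hz bands of the ovipositor ROI mean-intensity
trace (linear scale); `cwt1`–`cwt7` — natural-log Morlet magnitudes of
A5-stripe movement at seven log-spaced center frequencies from 0.5 to
10 Hz, floored at 1e-6. Movement channels are raw frame-to-frame Euclidean
displacements (px/frame), not velocity-smoothed. z-scoring is per
recording (per fly), not pooled across a cohort.

Open parameterizations resolved here: the wavelet is the complex Morlet
with the classic 6-cycle carrier (`cmor` with B = 2, C = 6/2π — the
standard admissibility/resolution trade-off); band channels average the
magnitude at four log-spaced frequencies spanning the band; the seven A5
channels are log-spaced because the band range spans 4.3 octaves. The ROI
pixel-intensity trace is an input (video extraction is out of scope; the
simulator supplies it); when absent, the wavelet channels fall back to the
ovipositor-keypoint displacement and the matrix is flagged.

Low-confidence keypoint frames (likelihood below `min_confidence`, default
0.9) are linearly interpolated from the neighboring confident frames,
leading/trailing gaps held at the nearest confident value, and the
interpolated spans recorded.

The walking classifier thresholds the 1-s centered moving average of the
scutellum speed at 0.29 mm/s (strictly greater); the moving window is
truncated at trace edges and averages over the frames available.

## Behavior map

The z-scored feature matrix is embedded in 2-D by t-SNE (perplexity 30,
PCA initialization, fixed seed) trained on a subsample (default 30,000
frames); remaining frames are placed at the embedding coordinate of their
nearest training neighbor in feature space. Nearest-neighbor placement is
the light-weight variant of re-embedding: it is deterministic, exact for
duplicated frames, and adequate when the training subsample covers the
occupied feature space.

Segmentation is a watershed on the negative of a kernel density estimate
of the embedding: a 512 × 512 histogram smoothed with a Gaussian whose
bandwidth defaults to Scott's rule on the training points, seeded at
density maxima; basins holding less than a minimum occupancy (default
0.5%) of frames merge into the neighbor sharing the longest border.

Cluster significance against expulsion locking uses a circular-shift null:
each event's label stream is rotated by an independent uniform offset,
which preserves the stream's composition and autocorrelation. The
statistic is the peak of the egg-out-aligned occupancy within ±20 s.
Occupancy courses are smoothed with a 0.5-s Gaussian before the peak is
taken — the raw per-frame occupancy is an integer count over events, and
ties between observed and null peaks would otherwise make the add-one
p-value conservative (the un-smoothed variant rejects at ≈ 0.02 for a
nominal 0.05); with smoothing the statistic is effectively continuous and
the test calibrates to its nominal level. A cluster is reported as
expulsion-locked if `p < α` *and* the peak of its wider (±60 s,
coverage-based) time course falls within ±20 s of expulsion. This null is
a stated substitute for the original analysis' unspecified test, not a
claim of equivalence.

Cluster ↔ behavior correspondence is frame-wise F1 per (cluster, behavior)
pair, each cluster assigned its argmax behavior, exact ties broken toward
the rarer behavior.

## Calcium pipeline

ΔF/F₀ = (F − F₀)/F₀ with F₀ the per-ROI median fluorescence from recording
onset to 20 s before completed expulsion, excluding ±20 s around each
ovipositor-extrusion event; without an expulsion anchor the window is the
whole trace minus exclusions. A 3-point moving average exists for display
only and never enters analysis. Distances are normalized by the median
T6–analia distance (a rigid anatomical reference), which maps to 1.

Event detection: the normalized distance trace is high-pass filtered at
0.001 Hz, TV-regularized, and event onsets are the upward crossings of one
fifth of the regularized maximum, with crossings within 1 s merged. The
high-pass is implemented as zero-phase subtraction of a centered
moving-average baseline whose length matches the cutoff (N = 0.443/(f·dt));
at these cutoffs this reduces to mean subtraction and avoids the large edge
transients a recursive filter develops when its pole sits at 1 − 10⁻⁴ of
unity. The TV step solves the exact 1-D proximal problem by Condat's
direct algorithm (O(n), no iteration tolerance), implemented here because
no installed library exposes an exact 1-D solver; it is cross-checked in
the tests against the bounded-least-squares dual of the TV problem. The
regularization weight defaults to 5× a robust noise estimate (median
absolute first difference / (√2·0.6745)); a trace whose regularized peak
stays below 4 noise sds is declared event-free. Crossing positions are
refined by a local least-squares step fit (±1.5 s window, iterated to
convergence), which localizes an abrupt step at 5:1 SNR to within ±2
frames essentially always. Upward crossings only: the tracked distances
increase as the egg or ovipositor advances; the direction is configurable.

Response magnitudes are trapezoidal integrals of ΔF/F₀ over [0, 3] s after
each onset, computed as a sliding integral at every frame. For the
incomplete-vs-complete expulsion comparison, the 0-anchor is the median
sliding integral over the first contiguous 60 s before complete expulsion
(excluding ±20 s around expulsion events), and the 1-anchor is the maximum
3-s integral observed anywhere in the trace — per ROI, matching per-neuron
rows in event-triggered displays; whether that maximum should instead be
per fly was ambiguous, and per-ROI is the implemented reading. For the
extrusion comparison the 0-anchor is the median over the first 60 s of
valid (possibly non-contiguous) frames starting 10 s after expulsion,
excluding ±20 s around extrusions. Values are mapped so anchor0 → 0 and
anchor1 → 1 and are *not* clipped: values outside [0, 1] are meaningful.
ROIs with multiple events are reduced by the mean. An identically-quiet
ROI (coincident anchors, all event integrals at the anchor) normalizes to
0; any other coincident-anchor case is an error. Event-triggered averages
pool per-ROI snippets over [−10, +20] s, edge-padded with NaN, with
NaN-aware mean and s.e.m.

## Agreement

Frame-wise TP/FP/FN per behavior after expanding pe and egg-out from one
to three frames in both annotations (width must be odd; clipped at the
bounds). F1 = 2PR/(P+R), with 0/0 defined as 0 and logged. "All behaviors
combined" is read as micro-averaging (pooled counts); the macro average is
reported alongside since the intended reading was not stated.

## Synthetic data: what it emulates, and what passing means

The ethogram generator is a semi-Markov chain over the seven behaviors:
onsets drawn from a 7 × 7 start-transition matrix, gamma dwell times, one
expulsion per event (the chain runs to expulsion, then up to 10
post-expulsion onsets, stopping before a second expulsion — a trailing
burrow bout is trimmed since it belongs to the next egg's attempt). Each
bout ends one frame before the next onset so consecutive same-label onsets
produce distinct bouts, and bend activity is extended across consecutive
burrow/expulsion/detach bouts to realize the overlap convention. Burrow
bout durations are cycle-driven: the cycle count is geometric with
per-cycle abort probability 0.25 and duration = cycles / rate (rate
1.2 s⁻¹) plus small noise, so duration and cycle count are correlated by
construction. With abort probability 0 the chain routes burrowing straight
to expulsion, so no episode ever aborts. The default transition matrix
mirrors the qualitative structure of the real sequence — a pe↔walk
exploration loop, walk→bend, bend→burrow, a burrow self-loop,
burrow→egg-out→detach→groom — with free parameter values chosen so that a
200-event cohort visits every pre-phase row often enough (≥ ~500
transitions) for the 0.05 recovery tolerance to sit several standard
errors out; no claim of numeric equality to any measured matrix is made.

The keypoint generator realizes walking as whole-body translation at
3 mm/s with a drifting heading, bending as rotation of the abdominal
keypoints about the A2 stripe, burrowing as an ROI-intensity sinusoid
whose frequency falls linearly across each episode (2.0 → 0.8 Hz,
emulating the slowing as the egg emerges), expulsion as an egg-confidence
ramp to 1, plus Gaussian jitter. The fluorescence generator uses a
double-exponential transient (rise 0.15 s, decay 0.8 s) peak-normalized to
the configured ΔF/F amplitude, shared slow drift between channels, white
noise, and rectangular distance excursions at event onsets. Egg-depth
tables draw per-fly Poisson(+1) egg counts with depth-category
probabilities per substrate firmness (softer substrates take deeper eggs).

These generators share the pipeline's vocabulary but are simplifications:
no measurement dropout or identity switches in keypoints, no bleaching or
motion artifacts in fluorescence, no behavioral lapses or inter-fly
heterogeneity in the chain. Passing the recovery benchmarks therefore
demonstrates the estimators' correctness and calibration under their
stated assumptions — not robustness to every artifact of real recordings.

## Benchmark problem sizes

The packaged benchmarks use: 200 events for transition recovery (max
absolute error < 0.05 over pre-phase-visited rows); 500 null datasets of
30 × 100 i.i.d. labels at 999 shuffles for permutation calibration; 100
traces × 10 step events at 5:1 SNR for detector fidelity (±2-frame
tolerance); tones at all nine band centers at 64 Hz sampling for wavelet
selectivity; 50 random traces for the walking oracle; 10,000 frames with a
5,000-frame training subsample for map purity; 150 replicates × 40 events
for the significance null; 100 random ethogram pairs for the F1 oracle; 20
constructed photostimulation trials; 48 flies per firmness level for
depth recovery. These sizes make each benchmark's statistical resolution
comfortably finer than the property it checks while keeping the full suite
runnable in a few minutes on one core.
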