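# Methods

`navtrace` implements an analysis of real-world outdoor GPS navigation
designed to discriminate people with Alzheimer's-type navigation
impairment from healthy controls. The underlying study data (two weeks
of body-worn GPS logging per participant) are private, so the package
ships a synthetic cohort generator with the same statistical structure;
every pipeline stage is exercised end to end against it.

## The unit of analysis: return-loop segments

A *segment* is a contiguous sub-trajectory whose first and last samples
lie within a slack radius (10 m) of each other — the person returns to
where they started — lasting between 1 and 20 minutes and covering at
least 100 m of path. The duration ceiling discards whole-day traces;
the duration and length floors discard jitter while stationary. These
four thresholds are exploratory constants, collected in `RunConfig`.

Extraction is a greedy earliest-start scan within each recording bout:
candidate endpoints at a start sample are all later in-bout samples
within the slack radius (found with a KD-tree but defined purely by the
distance predicate); among endpoints satisfying the duration window and
length floor, the one maximising path length wins (ties to the later
endpoint), and the scan resumes after the emitted loop, so segments
never overlap in time. The global selection order is not forced by the
definition; the greedy earliest-start policy was chosen because it is
deterministic, single-pass, and honours both the non-overlap and
maximum-length rules. Segments never span recording bouts: a loop
interrupted by a device-off gap is not a loop we can measure.

Because the tracker is worn only outside the home, traces consist of
short recording bouts separated by long gaps. Bouts are maximal runs
with inter-sample gaps ≤ 60 s (20× / 12× the nominal 3 s / 5 s sampling
interval) — long enough to bridge signal dropouts, short enough to
separate outings.

## Coordinates

Geographic coordinates are projected per participant onto a local
azimuthal equidistant plane centred on the median position. Radial
distances from the centre are exact on the sphere and pairwise planar
distances agree with geodesics to ~3×10⁻⁵ relative error at 50 km. (A
plain equirectangular map with a fixed cos(lat₀) scale was considered
and rejected: at 52°N its metres-per-degree-longitude factor drifts by
~0.22% per 0.1° of latitude, which already violates a 0.1% distance
budget a few km from the centre.)

## Features

**Mobility domain** (100 m × 100 m grid, anchored at the projection
origin, half-open cells):

- *Segment entropy* — Shannon entropy (nats) of the pooled cell-visit
  distribution over a participant's segments. Every sample contributes
  one count, weighting cells by time spent; cells never visited carry
  no mass. Natural log is used; the value is then bounded by ln(number
  of visited cells). Per-crossing counting is available as an option.
- *Segment similarity* — two segments are similar when the Jaccard
  similarity of their cell sets exceeds 0.5; each segment's feature is
  the fraction of the participant's *other* segments similar to it
  (self-pairs excluded — including them would floor every value at
  1/N). Undefined for participants with a single segment.
- *Distance from home* — home is the centroid of each recorded day's
  first and last positions (the tracker goes on and off at the front
  door); the feature is the Euclidean distance from home to the
  segment's centroid. Days are resolved in UTC.

**Spatial shape** (per segment): first-order turning angles are
counterclockwise rotations between consecutive displacement vectors, in
[0, 360); second-order angles use stride-2 vectors. Exactly repeated
consecutive points are merged before angle computation (zero-length
vectors have no direction). *Segment complexity* counts samples where
the mean of the first- and second-order angle magnitudes (each folded
to [0, 180]) exceeds 120°; using magnitudes makes the count invariant
to reversing the direction of travel. *Total turning angle* is the sum
of sines of the first-order angles — signed, positive for
counterclockwise-majority turning, and threshold-free. *Radius of
gyration* is the RMS distance of the segment's samples from their
centroid.

**Temporal**: *stop durations* are detected by a greedy anchored
window — extend while every sample stays within 10 m of the anchor;
record the window when its span reaches 60 s, else advance one sample.
"Location does not change" is operationalised as a radius test because
raw GPS positions jitter even when the person is still; the 10 m radius
matches the segment slack scale.

**Mobility graph**: the whole trace (all segments, alone and
accompanied) is coarsened to grid cells; every occupied cell is a node
and every observed consecutive-sample transition an undirected edge
(repeated transitions collapse; the centralities used are undirected
notions). Dwell time accumulates per cell with each inter-sample
interval split evenly between its two endpoint cells — the symmetric
split makes the graph exactly invariant to reversing the trace's time
direction, which a first-endpoint attribution would not be. Intervals
across recording-bout gaps are unobserved and attributed to no cell.
Cells dwelt in less than 5 min (cumulative) are transit: they are
removed in ascending (dwell, cell) order — a fixed order, since clique
insertion can depend on it — and each removed node's current
neighbours are pairwise reconnected, so connectivity through transit
corridors survives. Node importance is summarised by closeness
(component-scaled Wasserman–Faust form, so disconnected graphs are
handled), normalised betweenness, and degree centrality; participants
with fewer than 10 nodes are excluded from graph-based analyses.

**Participant vectors**: scalar features (entropy, node count) enter
classifiers directly (z-scored on the training fold); value-list
features become 10-bin normalised histograms. Histogram ranges span the
pooled *training* values of each cross-validation fold and are applied
frozen to the held-out participant, so the held-out data leak nothing
into the representation. Bin edges are half-open with the last bin
closed; out-of-range values clip into the terminal bins.

## Group statistics

Per-segment (or per-node) values are pooled across each group's
participants and compared with the two-sided two-sample
Kolmogorov–Smirnov test (asymptotic p-values), plus Cohen's d with the
(n−1)-weighted pooled SD. No multiple-testing correction is applied;
the per-feature p-values are reported as-is. For the spatiotemporal
comparison and classification, controls contribute all segments while
patients contribute only diary-labelled alone segments and must have
strictly more than five of them; the graph task instead keeps all
segments and requires ≥10 graph nodes.

## Classification

*Patient vs control*: logistic regression trained by plain stochastic
gradient descent — logistic loss, no penalty, constant learning rate
10⁻³, standard-normal random initialisation, 10,000 single-sample steps
with indices drawn uniformly with replacement — evaluated
leave-one-participant-out. The optimiser is deliberately stochastic and
budget-limited rather than converged: the protocol repeats every
experiment 50 times and reads the spread of the held-out class
probabilities as prediction uncertainty (mean over participants of the
SD of their 50 probabilities). A participant is predicted control when
P(control) > 0.5. Sensitivity and specificity use predicted-class
denominators: sensitivity = true patients / predicted patients,
specificity = true controls / predicted controls; a run predicting an
empty class leaves that rate undefined (excluded from the median).
The 50 runs are advanced in lockstep, vectorised over runs; the whole
report is bit-reproducible under a fixed master seed. (scikit-learn's
SGDClassifier always initialises at zero, which cannot express the
random-initialisation uncertainty this protocol measures — hence the
in-package optimiser; `LogisticRegression` serves as an independent
cross-check in tests.)

*Alone vs accompanied*: patients' segments pooled across participants,
raw per-segment features (complexity, total turning angle, stop count,
distance from home) standardised on the training split, RBF-kernel SVM
with library-default settings (C = 1, γ = 1/(p·Var)), 20 random 80/20
splits, median test accuracy. Splits leaving a class absent from
training are redrawn.

## The synthetic cohort generator

The generator emulates the study conditions: 18 controls and 15
patients, 14 days, 13 controls and 8 patients sampled at 3 s and the
rest at 5 s, home-anchored round trips with a persistent destination
set, Zipf-weighted (exponent 1.0) revisit probabilities, route reuse,
destination dwells of 1–8 min, and stationary AR(1) positional error
(stationary SD 5 m, 60 s decay; white noise as a special case). Real
GPS error is dominated by slowly drifting bias; i.i.d. noise of this
magnitude would make a 10 m static-radius stop detector essentially
never fire, erasing a feature the method relies on.

Group contrasts are injected only through effect parameters, all in the
documented directions: patients get fewer destinations (4 vs 10), a
smaller destination-distance scale (×0.25), and higher route reuse
(0.9 vs 0.08); their accompanied outings (half of outings) gain hairpin
side-spurs and counterclockwise detour loops (higher complexity and
signed turning) and extra mid-route pauses (more stops). Patients
travel at walking/cycling pace (≤8 m/s) while controls mix fast
transport (≤40 m/s) — which also keeps patients' movement shape
resolvable at the 3–5 s sampling interval. Travel legs, dwells and
pauses are budgeted so outing loops stay under the 20-minute segment
ceiling.

Several structural choices exist specifically so that, with the effect
parameters set to group-equal values (`null_config`), pooled
per-segment feature values behave approximately like i.i.d. draws and
the pooled KS test is approximately calibrated (measured: ≥95% of
per-feature null p-values above 0.05 over 40 seeded replicates):

- destination distances follow a deterministic per-rank ladder
  (exponential quantiles × group scale, floored at 600 m so route
  identity is resolvable at the 100 m grid) shared by every participant
  of a group;
- destination bearings are evenly spaced per participant (random
  rotation plus jitter) — random bearings occasionally collide and
  merge two destinations' routes into one similarity class;
- fresh route variants are narrow detour loops through via points on an
  evenly spaced 30° direction ladder (radius max(0.6 d, 800 m)):
  variants of a destination are decisively dissimilar on the grid
  (measured worst pairwise Jaccard 0.43) while replays are trivially
  similar, and all route-persistent feature values sit on a
  deterministic (rank, variant) grid shared cohort-wide;
- each participant makes the same total number of outings (a shuffled
  day-count template summing to 35, each day still 1–4), fixing the
  denominator of fraction-valued features across the cohort;
- the zero-contrast twin also equalises the 3 s/5 s sampling mix and
  sets the accompanied fraction to zero (controls are never
  accompanied, and the alone-only filter would otherwise halve the
  patients' segment counts).

What passing on this generator does and does not show: the synthetic
cohort is deliberately *less* clustered at the participant level than a
real cohort would be — real people's destination sets, schedules, and
route idiosyncrasies vary far more, which makes pooled segment-level
tests anti-conservative on real data. Results here validate the
pipeline's correctness and sensitivity under its stated assumptions,
not the transportability of pooled-KS p-values to real cohorts. Routes
are free-plane piecewise-linear paths, not road-network-constrained
(the features under test are network-agnostic); noise autocorrelation
is a single AR(1) scale; and one side effect of the pace contrast is
that slow-moving patients accumulate more per-cell dwell, so their
mobility graphs have *more* nodes than controls here, unlike the
reference cohort.

## Problem sizes and numerical choices

Default analyses run the full study-scale cohort (33 participants,
~35 outings each, ~300k GPS samples). Integration tests use reduced
cohorts (4–5 per group, 4–5 days) and scaled-down classification
settings (6–10 runs, 800–6,000 SGD steps); the acceptance checks run
the full cohort with the full 50-run / 10,000-step protocol and 20
null replicates. Ties in KS inputs are handled by the empirical sup;
degenerate histogram ranges fall back to a unit interval; duplicate
timestamps keep the first row; zero-length displacement vectors are
merged before angle computation; all randomness flows from a single
master seed through `numpy.random.SeedSequence` spawning.

## Known limitations

- The alone/accompanied diary is taken as ground truth; labelling
  uncertainty is not modelled.
- Calendar days are resolved in UTC; a timezone option exists but
  daylight-boundary effects are untested.
- The graph dwell threshold interacts with sampling pace: dwell is
  time-based, so slower travellers yield denser graphs.
- Pooled two-sample tests ignore participant-level clustering by
  design (they mirror the published analysis); see the generator notes
  above for why this matters on real data.
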