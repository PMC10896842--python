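# Methods

This note documents the models, numerical choices and limitations of
`sostim`. It describes what the code computes; every number quoted is
produced by the test suite or `scripts/acceptance.py`.

## SO detection

Detection operates per channel on the zero-phase band-passed signal
(4th-order Butterworth, 0.1–4 Hz, forward–backward via second-order
sections). Candidate events are delimited by zero crossings: an event
spans from a positive-to-negative crossing through the negative
half-wave and the following positive half-wave to the next
positive-to-negative crossing. Crossing times are placed at the midpoint
between the two straddling samples. The four criteria are: trough
≤ −80 µV; max − min over the event ≥ 80 µV; negative half-wave duration
within 300–1000 ms; total event duration ≤ 10 s. We read "minimum wave
amplitude below or equal to 80 µV" in the standard SO convention of a
trough at or below −80 µV.

**Edge handling.** Zero-phase IIR filtering leaves transients at record
edges; candidates whose extent reaches within `edge_exclude` (default
5 s) of either end are discarded. The value approximates two effective
impulse-response lengths of the 0.1–4 Hz filter at its dominant
low-frequency pole and is exposed as a parameter.

**Artifact masks.** The two muscle-artifact rules are band-limited bin
statistics (bin RMS by default; mean power and summed absolute amplitude
are available as config options since the literature rules name only
"power"): 26.25–32 Hz / 4-s bins flagged above 4× the median of the 45
surrounding bins (window truncated at record edges), and 4–50 Hz / 5-s
bins flagged above 6× the per-channel median of all bins. Both masks
additionally require the bin RMS to exceed an absolute floor of 5 µV:
scalp EMG artifacts run tens of µV, and without the floor the purely
relative rules flag numerically tiny fluctuations on silent or
near-silent records (median ≈ 0). An all-zero median yields no flags.

**Outlier screening.** The trough amplitude referenced to the mean of
the filtered signal in ±10 s around the minimum is used for screening
only (the event retains its filtered trough amplitude). Pass 1 discards,
per electrode, events above mean + 4 SD of that electrode's referenced
amplitudes (electrodes with a single event are skipped — SD undefined);
pass 2 repeats the rule on the pooled survivors.

**Stage containment** is evaluated on the 30-s hypnogram epochs covering
the event's start and end; both must carry the requested stage, and no
covered epoch may be scorer-excluded.

## Co-detection clustering

Each event seeds a binary vector over the head electrodes: electrode c
is set when any SO trough on c lies within the symmetric ±400 ms
co-detection window of the seed trough (delays are measured
trough-to-trough, and co-detected events must themselves be detected
SOs). The events × electrodes matrix is clustered with k-means under
Hamming distance, which on binary data is the k-modes algorithm:
centroids are per-electrode majority votes (ties resolved toward 1), and
the total Hamming cost is provably non-increasing across Lloyd
iterations (asserted at run time). 200 random distinct-row
initialisations are run (early exit on a zero-cost solution) and the
lowest-cost solution kept. Empty clusters are re-seeded at the row
farthest from its assigned centroid.

Cluster labels come from centroid topography: **Global** is the centroid
with the greatest mean co-detection over all electrodes (ties broken by
cluster size); of the remaining two, **Frontal** has the larger
frontal-minus-posterior mean, and the last is **Local**. The
frontal/posterior electrode partition is user-supplied (YAML) or derived
from the built-in scalp layout (y > 0.2 / y < −0.2 in the normalised
head coordinates).

## Current-density representation

A CD matrix holds m = 1000/Δt time bins (Δt ∈ {20, 50, 100, 200} ms,
window −500…+500 ms around the trough) by n regions (default 17).
Flattened feature vectors are **time-major** (bin 0's regions first);
one shared indexing function serves the classifier, the feature weights
and the optimisation objective, so the orderings cannot diverge. CD
units are arbitrary but must be consistent: the forward model that
would fix an absolute scale is external. WCC and the classifier's
tree-split thresholds are scale-dependent in the sense that data and
simulation must share one scale; the synthetic transfer operator is
therefore normalised to unit mean absolute sensitivity. Per-SO matrices
are not normalised before averaging or classification by default (an
option exposes z-scoring), since no such step is part of the modelled
procedure.

## Forward model

The current a paradigm delivers is assumed linear in the instantaneous
waveform amplitude, so a montage is fully characterised by one n-vector
of region sensitivities at unit amplitude and the paradigm CD is the
outer product of the binned waveform with that vector. Waveforms are
defined on [0, 1] s, evaluated on a 0.1 ms grid (bin means via midpoint
sampling; relative error against closed-form sinusoid integrals is
below 1e-4), with families W1 (A, f, φ, O), W2 (three sinusoids + O, 10
parameters), W3 (square wave, +1 for the first D % of each period) and
W4 (cubic polynomial in t − φ). Phases are radians. GA bounds:
amplitudes and offsets [0, 1], frequencies [0.01, 4] Hz, phases [−π, π],
duty cycle [0, 100] %, polynomial coefficients [−1, 1].

## Classifier

Bagging: 100 decision trees, each fit on a with-replacement bootstrap of
the training rows; the ensemble posterior is the mean of per-tree class
probabilities and the predicted class its argmax. Hyperparameters
(minimum leaf size, fraction of features considered per split) can be
tuned by a seeded randomized search with inner 5-fold cross-validation;
the default is untuned trees, which saturate performance on the
synthetic conditions. Performance is the MCC of the pooled out-of-fold
confusion matrix of a stratified 5-fold split — pooling is stable under
the ~1:2 class imbalance, which is otherwise handled only through
stratification (no resampling). A zero factor in the MCC denominator
returns 0 with a warning (standard convention). Feature weights are
one-way ANOVA F statistics per feature between the two label groups;
constant features get weight 0.

## Genetic algorithm

Within the stated termination contract (stall: average relative change
of the best fitness over 50 generations ≤ 1e-6; cap: 100 × number of
parameters, counting the initial random population as generation 1) the
operator suite is: tournament selection (size 3), blend/intermediate
crossover on 80 % of pairs, per-gene Gaussian mutation (probability
0.15, SD 0.1 × parameter range, clipped to bounds) and elitism of 2,
population 200. Elitism makes the best-fitness trace non-increasing.
Objective: ε = Σ ωᵢ d(xᵢ, xᵢ*) / Σ ωᵢ with d the squared difference
(absolute difference available as a config switch; the squared reading
keeps the objective bounded below and differentiable at the optimum).
The same reading applies to WMSE, whose extra leading 1/n would
double-normalise against Σω and is dropped — this scales WMSE values but
not rankings. Grid cells are seeded from (master seed, cell index) so
results are reproducible and independent of evaluation order.

**Protocol selection** classifies each optimised cell's CD and returns,
among cells predicted global, the one with the highest posterior; if no
cell is predicted global the best posterior overall is returned with an
explicit flag. Posterior ties — common once the ensemble saturates at
1.0 — are broken by the weighted fit error (WMSE) and then by a stable
paradigm key, keeping selection deterministic and order-invariant while
preferring the genuinely better-fitting paradigm.

## Synthetic data

The generators stand in for restricted clinical recordings and external
forward solves; their defaults define the conditions under which the
acceptance suite runs.

- **EEG**: 16 channels of the built-in 10-20 layout, 128 Hz, 300 s,
  six SO events per minute over 1/f-shaped background noise of 15 µV
  RMS. Events are biphasic (negative 500 ms half-sine to −120 µV, then
  positive half-sine to +60 µV, per-deposit amplitude jitter 0.9–1.3×)
  and come in three types mixed 1:1:1 — global (all channels, trough
  delays ≤ 350 ms), frontal (anterior channels only) and local (a
  2-channel neighbourhood); with each global event seen everywhere, the
  event-level global fraction of one third matches the reported ~1:2
  global:non-global imbalance. Placement is jittered-regular with a
  guaranteed gap so planted events never overlap. Not emulated: real
  spindle/ripple content, non-stationary stage transitions, true EMG
  artifacts, volume-conduction correlations of the background — so
  passing detection tests demonstrates criterion-correctness and
  robustness to 1/f noise, not performance on clinical EEG.
- **CD datasets**: the global class mean is a cosine-tapered bump
  supported on |t| ≤ 100 ms around the trough (height 3 SD of the iid
  Gaussian feature noise, scaled by a smooth random region profile);
  the non-global mean is zero. This reproduces the empirical pattern
  that near-trough features carry the class-discriminative signal. A
  caller may substitute explicit class means — the end-to-end test uses
  a known paradigm's CD as the global mean, with noise SD set to
  (target RMS)/3 to keep the same 3 SD separation.
- **Transfer operator**: each region's sensitivity to a scalp position
  is a seeded mixture of 40 Gaussian radial basis functions with length
  scale 0.25 in the unit-radius head layout — comparable to the
  inter-electrode spacing, so neighbouring electrodes are correlated
  while distinct montages remain distinguishable. A montage's vector is
  the polarity-weighted sum over its four pads (swapping anodes and
  cathodes negates it); vectors are normalised to unit mean absolute
  single-electrode sensitivity.

## Problem sizes

The test and acceptance runs use: 300 s of 16-channel EEG for
detection; 180 co-detection rows for clustering recovery; 150/300
global/non-global CDs at Δt = 20 ms for the classifier; single-montage
GA recovery at Δt = 100 ms; and ten seeded end-to-end pipeline runs at
Δt = 200 ms over a 4-montage × W1 grid. These sizes keep a full run in
the minutes range on one CPU while leaving every statistic far from its
decision threshold.

## Known limitations

- The linear transfer abstraction ignores every non-linearity and state
  dependence of real transcranial stimulation; it reproduces the
  modelling assumption, not the physics.
- Imported CD/transfer data are trusted for scale consistency; the
  package validates shapes and labels only.
- Hamming k-means is a local optimiser; the 200-replicate restart is a
  heuristic against local minima, not a global guarantee.
- The montage search enumerates user-specified per-quartile candidates;
  it does not verify 10-20 geometric validity of the labels beyond the
  built-in layout.
- The classifier's posterior saturates on well-separated synthetic
  classes; real data would produce a more graded ranking of paradigms.
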