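# Methods

This note documents the models, estimators and numerical conventions
behind `eegdx`, the reasoning for every default that was genuinely open,
and what the synthetic cohort does and does not establish.

## 1. Synthetic cohort model

Each recording is a sum over the five EEG rhythms of band-limited
Gaussian sources plus white sensor noise.  For rhythm *b* with band
edges [lo, hi):

1. draw white noise, apply an AR(1) filter with coefficient
   `regularity`, band-pass (order-4 Butterworth, zero-phase) to
   [lo, hi), and normalise to unit variance — this is the source model
   for global, regional and private sources alike;
2. channel *i* in scalp region *g* (frontal / central / parietal /
   occipital) receives

       m          = modularity · (1 − coupling)
       shared_b,i = √(1 − m) · global_b + √m · regional_b,g
       x_b,i      = coupling · shared_b,i + (1 − coupling) · private_b,i

3. each `x_b,i` is rescaled so its variance fraction equals
   `band_power_profile[b]` (so realised relative band power tracks the
   profile by construction), bands are summed and scaled to
   `amplitude_uv`, and `noise_sd` · white noise is added.

Population inter-channel correlation is
`c²/(c² + (1 − c)²)` within a region and `c²(1 − m)/(c² + (1 − c)²)`
across regions (before the small noise correction), hence monotone in
`coupling`, exactly 1 at `coupling = 1` with zero noise, and ≈ 0 at
`coupling = 0`.  `modularity` controls the within/cross-region contrast
without affecting either extreme.

### Group defaults and how they were chosen

| parameter | CN | AD | role |
|---|---|---|---|
| band profile (δ,θ,α,β,γ) | .15,.12,.25,.28,.20 | .35,.25,.20,.12,.08 | slowing |
| regularity (AR1) | 0.2 | 0.8 | complexity |
| coupling | 0.70 | 0.60 | synchrony strength |
| modularity | 1.0 | 0.0 | synchrony organisation |
| fs / duration | 250 Hz / 120 s | same | cohort size |
| amplitude / noise_sd | 10 µV / 1.5 µV | same | scale |

The defaults are *study conditions*: they were calibrated once, on
held-out probe seeds, to realise the qualitative AD effect pattern —
delta/theta power up; beta down; all four entropies down; clustering and
small-worldness down; path length up — with comfortable margins, and
then frozen.  Magnitudes are configurable and are not estimates of
clinical effect sizes.  Two calibration findings shaped the defaults:

* **Small-worldness needs an organisation knob, not just a strength
  knob.**  With purely global coupling all channel pairs are equally
  correlated, thresholded graphs are Erdős–Rényi-like at every density,
  and σ ≈ 1 in both groups.  Worse, if sparser AD graphs inherit the
  modular structure, their few edges concentrate inside modules and σ
  *rises*.  Decoupling organisation (`modularity`) from strength
  (`coupling`) lets CN be modular and small-world (σ ≈ 9 at these
  defaults) while AD is weaker *and* spatially uniform (σ ≈ 1.1),
  matching the degraded network organisation reported in patients.
* **Ordinal-pattern entropy is governed by the fast residual spectrum.**
  At 250–500 Hz sampling, order-3 permutation entropy depends on the
  correlation structure of successive sample differences, which the
  highest bands dominate.  A CN profile dominated by a single alpha
  rhythm produces *more* regular ordinal sequences than the AD mixture,
  inverting the expected PermEn direction regardless of the AR(1)
  contrast.  The CN default therefore carries substantial broadband
  fast (beta/gamma) activity — consistent with every band above theta
  exceeding its AD counterpart — which restores a robust PermEn gap
  (≈ −0.04 nats) alongside the SampEn/ApEn/MSE gaps.

The recording amplitude (10 µV SD) is chosen so that ordinary 0.5-s
windows sit well below the 17 µV artifact threshold: the synthetic data
contain no simulated artifacts, and the rejection stage is exercised by
dedicated tests instead.

Per-subject seeds derive from `SeedSequence((master_seed,
subject_index))`, so cohorts are reproducible as a whole and per
subject, and changing the cohort size does not reshuffle earlier
subjects.

### What the generator does not model

No 1/f background continuum, no eye-blink/muscle/electrode artifacts,
no non-stationarity across the recording, no volume conduction or
dipolar topography, no age/severity gradients.  Group differences are
homogeneous across subjects except for sampling variability, which is
why classifiers reach ceiling accuracy here; passing tests demonstrate
that the estimators and the cross-validation protocol behave correctly,
not that clinical discrimination of this quality is attainable.

## 2. Preprocessing

Fixed stage order: re-reference → band-pass → artifact rejection →
epoching, applied exactly once per recording.

* **Re-referencing** subtracts the mean of A1/A2 and drops them
  (case-insensitive label match).  Recordings without mastoids — the
  synthetic default — pass through unchanged with a logged notice; a
  montage with exactly one mastoid is rejected as ambiguous.
* **Band-pass**: order-4 Butterworth, 0.5–45 Hz, applied
  forward–backward (`sosfiltfilt`) so the effective gain is |H(f)|² and
  no phase distortion biases the entropy estimates.  The order is a
  deliberate default: steeper filters buy stop-band attenuation at the
  cost of longer edge transients.
* **Artifact rejection** is the reproducible SD rule alone: consecutive
  non-overlapping 0.5-s windows; a window is excised if any channel's
  sample SD exceeds 17 (interpreted as microvolts of the calibrated
  signal; configurable).  Removing whole windows keeps the window grid
  aligned, making the operation idempotent.  A trailing partial window
  is never rejected.  Concatenation seams are an accepted artifact of
  this stand-in; no ICA or artifact subspace reconstruction is
  attempted.
* **Epoching**: length L = 4 s · fs, step L·(1 − overlap), overlap 0.5,
  grid anchored at sample 0 of the post-rejection recording; a trailing
  partial epoch is discarded; count = ⌊(N − L)/step⌋ + 1.

## 3. Spectral estimators

Welch PSD with 1-s Hamming segments and 50% overlap (7 averages per 4-s
epoch, ~1 Hz resolution), constant detrend.  Band energies integrate
the one-sided density by the trapezoid rule over each band's frequency
samples *augmented with linearly interpolated edge values*, so the five
bands tile 0.5–45 Hz exactly: RBP sums to 1 identically and a flat
density yields RBP proportional to band width.  The IQR uses the
linear-interpolation ("type 7") quantile convention; variance uses the
N−1 denominator.  A zero density (possible only for degenerate input)
raises and the epoch is dropped.

## 4. Entropy estimators

Conventions, all tested to 1e-10 against naive direct-from-formula
implementations:

* Chebyshev (max-coordinate) template distance; tolerance r =
  r_factor × population SD of the series it applies to.
* **ApEn** (m=1, r_factor=0.2): self-matches included, so counts are
  never zero; a constant series (r = 0 under the relative rule) is
  defined as 0.
* **SampEn** (m=2, r_factor=0.15): self-matches excluded, N−m templates
  at both lengths, −ln(B_{m+1}/B_m).  No match at length m+1 ⇒ NaN; the
  pipeline drops such epochs and logs the count.
* **PermEn** (n=3): stable argsort, ties broken earlier-index-first,
  natural log, unnormalised (range [0, ln n!]); an all-equal series has
  one pattern and entropy 0.
* **MSE** (m=2, r_factor=0.15, τ=5): non-overlapping block means, then
  SampEn with r anchored to the *original* series SD (configurable to
  per-scale r, and to averaging scales 1..τ, both off by default).  The
  coarse series must exceed m+2 samples — the bare SampEn minimum would
  rest on a single template pair.

The pairwise-counting kernels are numba-compiled; the oracles in the
test suite are plain numpy enumerations of the defining formulas.

## 5. Connectivity graphs

Absolute Pearson correlation on the broadband (0.5–45 Hz) epoch,
diagonal zeroed; constant channels get zero correlation with a logged
notice.  Binarisation keeps edges with |r| ≥ threshold (default 0.7,
boundary included).  Metrics operate on the adjacency matrix directly:

* clustering via triangle counts (A³ diagonal), C_i = 0 where k_i < 2;
* path length via unweighted BFS; **disconnected pairs are excluded**
  from L (connected fraction logged) and contribute 0 to efficiency —
  stated explicitly because textbook definitions assume connectedness;
* small-worldness σ = γ/δ against 20 degree-preserving rewired nulls
  (double-edge swaps, 10·|E| attempts, seeded).  A complete graph
  cannot be rewired: null = original and σ = 1.  σ is NaN (feature
  flagged missing, epoch dropped) when the graph or its nulls have zero
  clustering or no defined path length — at the AD defaults this
  affects ~0–5% of epochs.

At the CN defaults the modular graphs are often a union of
within-region cliques: L over *connected* pairs is then near 1 even
though the graph is fragmented, which is why efficiency (which does see
disconnection) and mean degree are reported alongside.  Known
limitation: at the frozen defaults, mean degree and efficiency come out
*higher* in the AD-like group — the uniform AD coupling sits closer to
the binarisation threshold than CN's cross-region correlations, giving
AD more (but unorganised) edges.  The three direction claims the
generator makes for synchrony are clustering ↓, small-worldness ↓ and
path length ↑.

## 6. Feature table, statistics, classification

Scalar features are computed per channel and averaged across the 19
channels (an `average_channels_first` switch offers the
average-the-signal-first alternative); the five graph features are
computed once per epoch.  Rows with any undefined feature are dropped
and counted.  The 18-feature vector is: mean, variance, iqr, five RBPs,
total power, four entropies, and five graph metrics — mean degree is
included to complete the synchronization family alongside C, L, E and σ.

Group comparison: Welch's unequal-variance t-test per feature at the
epoch level, significance stars at 0.05/0.01/0.001, no multiple-testing
correction (the stars describe single features, mirroring the
per-feature reporting convention).  Features constant in both groups
are excluded with a log entry.

LOPO evaluation: one fold per subject; standardisation parameters are
computed from training rows only (a test asserts the scaler never sees
held-out rows).  Classifier defaults, all configurable: decision tree
(Gini, unlimited depth), random forest (100 trees), SVM (RBF, C=1,
bandwidth from the median heuristic on standardised training rows).
Rates are percentages from the summed confusion counts; a
subject-level majority-vote accuracy is available as an explicitly
labelled extension beyond the epoch-level protocol.

A note on the permutation control: under LOPO, shuffling group labels
at the subject level produces slightly *below*-chance accuracy
(≈ 42% vs a 50% majority rate at the default cohort) — the well-known
anti-learning effect of leave-one-group-out validation with label
noise, since the held-out subject's class is always the minority of
what the model overfits to.  The control therefore sits ~8 points below
the majority rate in expectation.

## 7. Problem sizes and runtime

The default cohort (20 subjects × 120 s at 250 Hz → ≈ 1 160 epochs of
19 × 1 000 samples) was sized so the full pipeline — generation,
preprocessing, 18 features per epoch including the O(N²) entropies and
20-null small-worldness, statistics and three LOPO evaluations —
completes in a few minutes on one CPU while leaving every group
contrast far from marginal.  The entropy kernels are numba-JIT
compiled on first use (~1 s, once per process).

## 8. File formats

EDF writing uses 1-second 16-bit data records with per-channel
symmetric physical ranges re-parsed from their 8-character ASCII header
form, so quantisation in a round trip is bounded by the header
precision (±0.05 µV at typical amplitudes); a fixed start date makes
repeated writes byte-identical.  Reading goes through MNE.  The
delimited text format stores samples × channels with a label header and
a `#` metadata line (fs, subject, group); an explicit `fs` argument
overrides the metadata.  Cohort directories carry one file per subject
plus `subjects.csv` (subject_id, group).
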