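# Methods

## Overview

`micnet` analyses cue-based four-class motor-imagery (MI) EEG as a
functional-connectivity problem on a fixed 22-electrode 10–20 montage.  The
pipeline contrasts each imagery condition (left hand, right hand, feet,
tongue) against the pre-cue fixation baseline, edge by edge over the
22 × 22 channel-pair adjacency, and summarizes the surviving edges as a
simple undirected graph whose centrality and integration properties are
then reported.  Because no public recording accompanies the paradigm, the
package ships a synthetic-EEG generator that reproduces the recording's
statistical structure together with ground truth, so every stage is
testable end to end.

## Experiment model

A trial is: beep (t = 0), 2 s fixation cross (baseline window), 1.25 s
arrow cue, 2 s imagery window, ≈2 s inter-trial break — a 7.25 s footprint.
A session holds 6 sequences; each sequence presents every task 12 times in
randomized order (72 trials per task per session, 288 per session).  The
study population is 19 participants × 2 sessions ≈ 10,944 trials.  These
counts are the `SessionSpec` defaults; schedules are produced by
deterministic per-(participant, session, sequence) substreams of one seed,
so the same seed always yields the same randomized order and different
seeds permute only within sequences.

The inter-trial interval is fixed at its nominal 2.0 s (the protocol's
"around 2 s"); it is configurable but nothing downstream depends on it
beyond trial spacing.

Channel identity is positional: channel *i* is the *i*-th electrode of the
fixed recording order (Fz, FC1, FC3, FCz, FC2, FC4, T7, C3, C1, Cz, C2, C4,
T8, CP3, CP1, CPz, CP2, CP4, P3, Pz, P2, Oz).  Hemisphere assignment
follows the 10–20 suffix convention (odd → left, even → right, z →
midline), and an electrode *pair* is classed `left`/`right` only when both
endpoints are on that side; any midline endpoint or crossing pair is
`bilateral`.  This strict rule is a deliberate choice: published
hemisphere groupings of such tables are not always internally consistent,
and the strict rule is the only one that is well defined from the montage
alone.

## Synthetic recording

Each of the 22 EEG channels carries independent noise with a 1/f power
spectrum, floored below 0.5 Hz to mirror the acquisition band-pass
(0.5–100 Hz); the log–log PSD slope over 1–45 Hz is ≈ −1.  Inter-channel
dependence comes from latent band-limited oscillators: each coupled
electrode pair shares one unit-variance source built from band-pass
filtered white noise in the mu (10 ± 2 Hz) and beta (20 ± 5 Hz) bands,
mixed into both endpoint channels with weight `w`.  With per-channel noise
SD σ the expected zero-lag correlation of an isolated coupled pair is
`w² / (w² + σ²)`; the defaults (w = 8, σ = 10 µV) give ≈ 0.39, a realistic
sensor-space coupling level.  Oscillators are filtered noise rather than
sinusoids so correlations are estimable but bounded away from 1.

The default coupled edge set is the 19 frontocentral/centroparietal pairs
of the published tongue-contrast table, and the default condition effect is
`condition_scale = {"tongue": 0.3}`: during the 2 s imagery window of a
tongue trial the mixing weight drops to 0.3 w (coupling *reduction*, the
direction the study reports).  No effect size is published for this
reduction, so 0.3 is a free simulation parameter chosen once to give a
clearly detectable but not saturated effect; the generator also accepts
scales above baseline for power studies.  `ground_truth_edges` returns the
edges whose effective weight differs from baseline for a given task.

Artifacts are injected per trial at the study's reported rates (EOG 4.8%,
EMG 1.2% of trials).  An EOG artifact adds a 0.5–4 Hz burst scaled to
150 µV peak on the three EOG channels (which otherwise carry a shared
15 µV ocular source plus noise) with 30% leakage into the six frontal EEG
channels; an EMG artifact adds independent 30–100 Hz noise at 40 µV RMS on
all EEG channels.  Truth flags are recorded per trial.

What the generator does **not** emulate: volume conduction and field
spread, realistic source geometry or referencing artifacts, non-stationary
background rhythms, eye-blink waveform shape, or inter-participant
variability in effect size (all participants share the same latent model;
only the noise realizations differ).  Passing recovery tests therefore
demonstrate the *statistical* correctness of the pipeline under its own
assumptions, not performance on real EEG.

## Preprocessing

Filtering is zero-phase: a 4th-order Butterworth band-pass 0.5–100 Hz
applied forward–backward, then a 50 Hz notch (quality factor 30).
Zero-phase filtering was chosen to avoid latency distortion of the 2 s
analysis windows.  Epoching takes two half-open 500-sample windows per
trial at 250 Hz: baseline from the fixation onset (= trial onset) and
imagery from cue offset.  Trials extending past the recording end are
dropped with a warning.

Artifact rejection is threshold-based and validated against simulator
truth: a trial is EOG-rejected when peak |EOG| in its windows exceeds
100 µV, else EMG-rejected when its mean 30–100 Hz EEG band power (Welch)
exceeds 3× the session median.  Dual-artifact trials count once, under
EOG, which makes the three QC percentages exactly additive
(preserved = 100 − EOG% − EMG%).  ICA-based correction is deliberately out
of scope: it is an off-the-shelf method whose expert-guided component
selection cannot be reproduced faithfully, and threshold rejection is
sufficient for the simulated artifact classes (sensitivity ≥ 0.9, false
positives ≤ 5% at the default amplitudes).  The original study's rejection
criteria (expert visual inspection) are unpublished, so these thresholds
are pipeline choices validated only against the simulator.

## Connectivity

The condition adjacency is the per-epoch zero-lag Pearson correlation of
each channel pair over its 500 samples, averaged across kept epochs via
the Fisher z-transform (the standard way to average correlations).  A
configurable max-lag variant reports the signed maximum-absolute
cross-correlation over |lag| ≤ L, since the lag convention behind
published "cross-correlation coefficients" is rarely stated.  Whether to
average per-epoch correlations or correlate concatenated epochs is equally
unstated; per-epoch averaging is the default because it is robust to
between-trial level shifts.

Per participant, the off-diagonal entries of all five matrices (baseline +
four conditions) are pooled and affinely mapped to mean 0 and a target
variance, identically for every matrix of that participant.  The default
target variance is 1; a variance-3 mode exists because the normalization
is sometimes described that way, but the choice is immaterial downstream —
the paired t statistic is invariant to any common affine map, so q-values
do not change.

Coherence is computed by complex demodulation on the 0.5 Hz × 100 ms grid:
mix with `exp(−i2πft)`, low-pass the product (2nd-order zero-phase
Butterworth, 0.25 Hz cutoff matching the grid spacing, reduced pad length
for 2 s epochs), subsample every 25 samples, and form
`|⟨XȲ⟩|² / (⟨|X|²⟩⟨|Y|²⟩)` across epochs.  Coherence is scale-invariant by
construction and its null level is ≈ 1/n_epochs.  It is computed in sensor
space on the 22 electrodes; dipole source fitting and source-space
rendering are out of scope.  Binarized graphs are produced by thresholding
r or coherence matrices at configurable levels (default sweep 0.7, 0.8,
0.9), with edge sets nested by construction.

## Inference

The design is paired within participants.  For each of the 231 edges, the
participant-wise differences d_k = cond_k − base_k give a paired t
statistic; the null is built by sign-flipping the d_k — all 2^n flips
enumerated when n ≤ 12 (the p-value is then exact, count/2^n with the
identity included), otherwise n_perm Monte-Carlo flips with the
(1 + count)/(1 + n_perm) correction so p is never 0 and Benjamini–Hochberg
behaves correctly.  Sign-flip permutation assumes the differences are
sign-symmetric under the null, which holds for the paired baseline
contrast.  Group-level permutation of participants was the other
defensible reading of "permuted t-test"; the paired design was chosen
because the normalization is explicitly per participant and the contrast
is within participant.

BH q-values use the step-up formula q_(i) = min_{j≥i} p_(j)·m/j, capped at
1 (cross-checked against statsmodels to 1e−12).  The significance graph
takes edges with q < α (default 0.05), ranked by q with |t| as
tie-break, truncated to the top_k (default 19, mirroring the published
table's reporting depth; both configurable).  Effect sizes are paired
Cohen's d = mean(d)/sd(d) with sample SD; zero-variance differences are
flagged undefined.  Direction is the sign of the mean difference.

## Graph metrics

Standard definitions on the simple undirected unweighted graph: degree;
shortest-path betweenness (raw unordered-pair counts and the
(n−1)(n−2)/2-normalized variant — both are emitted because published
values rarely state the convention); Latora–Marchiori global efficiency
(mean inverse shortest-path length, 0 for disconnected pairs); and local
efficiency (global efficiency of each vertex's neighbor-induced subgraph,
0 below 2 neighbors).  Under these definitions both efficiencies lie in
[0, 1]; published efficiency magnitudes above 1 cannot arise from them and
no attempt is made to match such values.  The degree summary excludes
isolated vertices by default, which is the natural population for a sparse
significance graph.  Implementations are networkx; tests verify them
against an explicit brute-force shortest-path enumeration on hundreds of
small random graphs.

## Problem sizes and numerical choices

* End-to-end recovery runs (tests and the acceptance script) use the full
  19-participant population but a shortened session — 1 session × 2
  sequences = 96 trials (24 per task) per participant — which keeps a
  replicated full-pipeline study at a few minutes while leaving the paired
  test its full n = 19.  Generator defaults remain the complete design
  (2 × 6 sequences).
* Type-I calibration uses 200 exact-null replicates of 19 × 231 Gaussian
  difference matrices with 1,000 sign-flips at α = 0.05.
* Fisher z-averaging clips |r| at 1 − 10⁻⁶ to keep atanh finite; epochs
  where a pair is undefined (constant channel) are excluded from that
  pair's mean, and an all-undefined pair raises.
* Permutation tie handling: |t*| ≥ |t| is evaluated with a 10⁻¹² tolerance
  so exact sign-symmetric ties are always counted.
* All randomness descends from one integer seed through
  `numpy.random.SeedSequence` spawn keys (per participant/session/
  sequence), so outputs are bit-reproducible; the pipeline manifest records
  the seed and a config hash.

## Known limitations

* Group statistics of the original study (its t, d, efficiency means,
  per-edge q-values) depend on unreleased recordings and are not
  reproducible; the package instead validates the arithmetic whose inputs
  are fully printed and the statistical properties the method must have.
* Sensor-space correlation is susceptible to volume conduction on real
  EEG; the generator does not model field spread, so this caveat is not
  exercised by the tests.
* The recording container is a flat float32 binary + JSON header + events
  TSV; EDF export is not provided.
* Coherence uses a short zero-phase IIR low-pass on 2 s epochs; its
  effective frequency resolution near the 0.5 Hz grid spacing is limited
  by the epoch length.
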