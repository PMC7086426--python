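# Methods

## Problem and pipeline

The package detects moderate traumatic brain injury (TBI, Glasgow Coma
Scale 9–13) from resting-state eye-closed EEG. The classifier operates on
raw one-second amplitude matrices — no filtering, no feature engineering —
and is evaluated the way small clinical cohorts demand: subject-level
threefold cross-validation, repeated over bootstrap resamples of the
cohort, reported as mean accuracy, SD, and a 95% percentile interval.
Four feature-engineered baselines (Naive Bayes on beta power and envelope
connectivity; AdaBoost on frontal log-PSD; an RBF SVM on MRMR-selected
band/bin powers; an RBF SVM on alpha power) share the same estimator
contract so the comparison runs under one cross-validation harness.

Data preparation follows the acquisition protocol: of 64 WaveGuard
10-10 channels, CPz is wired as EOG and excluded (63 analysis channels);
the first 60 s of a recording are discarded as settling time; the next
60 s are cut into sixty non-overlapping one-second segments. Each segment
is the matrix `M[i, t] = x_i(t)` — channel `i`'s amplitude (µV) at sample
`t` — so the clinical geometry yields 63 × 1000 inputs. Trailing partial
windows are floored away. Manual artifact inspection is replaced by an
optional deterministic amplitude-threshold rejector (default 100 µV when
enabled; off for synthetic data, which contains no artifacts).

## Network topology and shape algebra

The reference network is nine layers: five 5×5 stride-1 valid convolutions
(6 filters each, each followed by batch normalization then ReLU), a 2×2
stride-2 average pooling, a sixth convolution, a second pooling, and a
dense softmax readout of 2 logits. Shapes propagate by

    h' = ⌊(h − f + s)/s⌋,   w' = ⌊(w − f + s)/s⌋

with depth set by the filter count (convolution) or preserved (pooling).
The floor is forced by the printed trace (43 rows pooled 2/2 → 21, not
21.5), and padding is absent for the same reason. On 63 × 1000 the trace
is 59×996×6, 55×992×6, 51×988×6, 47×984×6, 43×980×6, 21×490×6, 17×486×6,
8×243×6, then an 11664-element flatten into the dense layer. The topology
is data (`TopologySpec`, YAML-serializable); `trace_shapes` validates any
candidate before weights exist.

Open choices resolved here: batch normalization precedes ReLU (order of
mention); the pooling recurrence is the same pair of equations applied
with f = s = 2; no hidden dense layers are added.

## Training regime

SGD with momentum: `v ← m·v − lr·(∇ + λw)`, `w ← w + v`, with the
reference constants lr = 1e-4 (constant), m = 0.9, λ = 5e-4 (applied to
convolution and dense weights only), mini-batch 128, 30 epochs; an epoch
is ⌈n/batch⌉ iterations (680 segments → 6). The loss is two-class
cross-entropy plus `0.5·λ‖w‖²`. Weight initialization (unstated in the
source protocol) is fan-in-scaled Gaussian; initialization and the
per-epoch shuffle draw from one seeded generator, so a (data, seed) pair
fixes the entire trajectory — asserted by test.

The implementation is a compact numpy stack (channels-last, float32,
im2col convolutions through BLAS). Gradients are verified against central
finite differences in double precision; the one analytic zero (a
convolution bias feeding batch normalization) is excluded from that check.
The first convolution's input gradient is never consumed and is skipped.

## Evaluation protocol

Segments are samples, but folds split *subjects*: no subject's segments
straddle train/test. Accuracy is `100·(TP+TN)/(TP+TN+FP+FN)` with TBI
positive. Two fold schemes exist: the literal 15+15 assignment (fold 1
tests subjects 11–15 of each class, fold 2 tests 1–5, fold 3 tests 6–10)
and a seeded class-balanced random scheme used inside the bootstrap.

The bootstrap resamples subjects (not segments) with replacement to the
original cohort size; a subject drawn m times contributes its segments m
times on whichever side of each split its identity lands, preserving the
no-leakage guarantee. Each iteration runs a balanced threefold CV and
records the mean fold accuracy; the result is summarized by mean, sample
SD (n−1), and the 2.5th/97.5th percentiles (percentile CI — the
assumption-free default, adopted because no printed interval constrains
the choice). Resamples missing a class are redrawn and counted.

## Synthetic cohorts

Because the clinical data are restricted, cohorts are generated with the
class structure the detection problem assumes: per channel, 1/f^β
background noise (β = 1 default) plus band-limited Gaussian oscillations
(delta 3, theta 4, alpha 8, beta 2 µV RMS — an eyes-closed,
alpha-dominant profile in the plausible 10–50 µV total range), per-subject
lognormal amplitude factors (CV 0.2), and nearest-neighbour channel
mixing (0.5) so connectivity features are nondegenerate. The injured
class multiplies alpha amplitude by `alpha_attenuation` and theta by
`theta_gain` — the attenuated-alpha / elevated-theta biomarker direction.
`alpha_attenuation = theta_gain = 1` is the null cohort. Defaults
reproduce the clinical geometry (15/class, 64 ch, 1000 Hz, 130 s — 130 so
the 60 s discard + 60 s analysis fits with margin).

What the generator does *not* emulate: ocular/muscle artifacts (beyond
the injected test spike), volume conduction through a head model,
non-stationarity, electrode noise, or the reported alpha *frequency*
shift (the effect is implemented as band amplitude, not peak location).
Passing tests therefore certify the pipeline's machinery and its ability
to recover a known spectral effect — not clinical performance.

## Desk-scale study configuration

Full-geometry training (63 × 1000 segments, 60/subject) is hours of CPU
work per cross-validation; the routine test/verification configuration is
scaled down once and fixed: 20 channels (19 after CPz exclusion) at
128 Hz, 16 s per subject → ten 1 s segments after a 4 s discard; a
compact variant of the topology (5×5 conv, 5×5 conv, 2×2 pool, 3×3 conv,
2×2 pool, dense; 3 filters per convolution) with a shorter, hotter regime
(lr 0.02, batch 32, 12 epochs). Under these conditions the CNN's
threefold CV on a cohort with `alpha_attenuation 0.4, theta_gain 1.5`
reaches the mid-70s% range while the null cohort's 20-iteration bootstrap
stays within the binomial chance band — the two behaviours the acceptance
suite asserts. The effect-monotonicity property is exercised at its
endpoints (null and 0.4); the 0.7 midpoint is not routinely run.

## Numerical and design notes

- Band ranges (unstated in the source protocol): delta 0.5–4, theta 4–8,
  alpha 8–13, beta 13–30 (beta1 13–18, beta2 18–24, beta3 24–30), gamma
  30–70 Hz (the amplifier's 70 Hz ceiling). Notch default 50 Hz.
- Band power integrates a Welch spectrum over [low, high); bands beyond
  Nyquist raise. Filter chains degrade gracefully: a low-pass at or above
  Nyquist is a no-op, band-pass high edges clip to 0.99·Nyquist.
- Envelope connectivity: band-filter, orthogonalize one analytic signal
  against the other (remove the zero-lag parallel component), correlate
  log envelopes. Identical inputs return 0 by convention (the shared
  component is everything); a constant reference envelope (pure tone)
  raises as undefined. The Naive Bayes pipeline aggregates to
  per-electrode mean connectivity per band; the pairwise primitive is
  public for full-matrix use.
- MRMR: mutual information on 4-bin equal-frequency discretized features;
  greedy relevance-minus-mean-redundancy; ties break to the lowest index;
  constant features are never candidates.
- SVM baselines standardize features on the training fold only; RBF
  kernel, C = 1 (unstated upstream; conventional defaults).
- EDF files are written with one-second records, per-channel physical
  ranges, and 16-bit quantization (round-trip error ≤ one step); reading
  goes through MNE. The plain-matrix interchange format is TSV plus a
  `key: value` sidecar.

## Limitations

- Reported clinical accuracies (e.g. 72.46% mean CV accuracy) require the
  restricted cohort and are not reproduction targets here.
- Per-segment classification only; no subject-level vote is defined or
  applied.
- The desk-scale CNN is a reduced topology; only the full nine-layer
  shape arithmetic — not full-scale training behaviour — is verified
  exactly.
- Bootstrap CIs at 20 iterations are coarse; 100 iterations (the
  protocol's value) is the default outside the scaled-down null check.
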