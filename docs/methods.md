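# Methods

This package implements a pipeline for classifying visual-stimulus
categories from high-density EEG: swarm decomposition (SWD) of each
channel into oscillatory modes, spatial clustering of electrodes into the
19 regions of the 10–20 system to form image-like tensors, and a small
convolutional network for 2-class (`Bul` vs `NoBul`) or 4-class
(stimulus × presentation context) problems. Because recordings of this
kind are not publicly distributable, the package is driven end to end by a
synthetic HD-EEG generator whose statistical structure matches what the
pipeline assumes; this note records the models, parameter choices and
their limits.

## Synthetic HD-EEG generator

Each trial is `channels × samples` (default 256 × 256 at 250 Hz, i.e. a
~1 s epoch; 17 subjects × 7 trials per class by default, giving the
T1-like 256 × 256 × 14 × 17 session tensor). A trial is the sum of:

* **Background**: per-channel Gaussian noise with power spectrum
  ∝ 1/f^α, α = 1.0 (the typical broadband EEG slope), normalized to unit
  RMS. Channels are spectrally realistic but spatially independent — real
  EEG has strong volume-conduction correlations that the generator omits
  (see Limitations).
* **Class effects**: for each `(group, f₀, amplitude)` entry of the
  class's effect list, a Hann-windowed sinusoidal burst (40 % of the trial
  long) of amplitude `amplitude × effect_scale` is added to every channel
  of that anatomical group, with per-trial random phase shared across the
  group (a spatially coherent oscillation) and onset jittered uniformly —
  so neither absolute phase nor a fixed latency is informative. Default
  2-class effect: 10 Hz (alpha) bursts over the centro-parietal groups
  C3/Cz/C4 for `Bul` trials; the 4-class default adds a 20 Hz frontal
  burst marking the immersive-context classes.

Groups are defined generatively as nearest-anchor regions: each electrode
belongs to the closest of the 19 canonical 10–20 positions. This is the
ground truth that the clustering stage is expected to recover.
`effect_scale = 0` is an exact null: labels are assigned to statistically
identical trials. Layouts place the 19 anchors at their idealized
unit-sphere coordinates and fill the rest of the upper hemisphere with a
Fibonacci lattice; electrodes are stored in a seed-shuffled order because
hardware channel numbering on a geodesic net is not spatially sorted (this
also makes the clustering reorder a real intervention rather than a no-op).

## Preprocessing

Fixed chain, in order: zero-phase 0.3–30 Hz bandpass → per-channel
normalization → zero-phase 7 Hz highpass → polyphase resampling to 128
samples. Filters are 4th-order Butterworth run forward–backward; cutoffs
are the conventional acquisition band and a 7 Hz floor that removes slow
content which otherwise dominates the first extracted modes.
Normalization subtracts the channel mean and divides by the maximum of the
*mean-subtracted* signal, which guarantees max = 1 regardless of sign
conventions (dividing by the raw maximum breaks on negative-mean
channels); constant channels cannot be normalized and are zero-filled with
a warning. Resampling is rational-factor polyphase (256→128 is 1/2,
192→128 is 2/3), i.e. anti-aliased, never naive decimation. Baseline
correction is available as a helper but is not in the default chain — the
generator emits segmented, baseline-free trials.

## Swarm decomposition

The swarm filter models M agents pursuing the input sample stream: each
agent's velocity is updated by attraction to the target and to the swarm
mean with coefficient δ, with a velocity leak (1 − 1/M), and positions
integrate velocities. All agents start from rest at the origin, so they
move in lockstep and the aggregate obeys the second-order recursion

    v[n+1] = ρ·v[n] + δ·(s[n] − x[n]),   x[n+1] = x[n] + v[n+1],

with ρ = 1 − 1/M — a damped resonator with poles of radius √ρ whose
center frequency is set by δ and whose bandwidth by M. The leak is
essential: without it the pole determinant is exactly 1 (an undamped
resonator), iterated filtering diverges at resonance, and no parameter
pair admits a convergent mode extraction. The filter is linear,
deterministic, and maps zero to zero; inadmissible (M, δ) pairs are
detected as instability (output exceeding 10⁶ × the input peak) and
reported with the offending pair.

**Calibration.** The mapping from a target normalized frequency to (M, δ)
is built once per process by probing: unit sinusoids over a fine frequency
grid measure the empirical gain curve of every candidate pair
(M ∈ {4, 6, 8}, 400 log-spaced δ per M), and each frequency bin of a
0.0125-spaced lookup grid receives the stable pair whose gain peaks
nearest the bin (ties to smaller M, then smaller δ). The fine bin spacing
keeps the filter center within half a Welch bin of the estimated dominant
frequency; M ∈ {4–8} was chosen because much broader filters absorb
neighboring tones into one mode and much sharper ones distort short
epochs with edge ringing. The table is cached and versioned.

**Mode extraction.** For the running residual: estimate the dominant
frequency by Welch periodogram (Hann window 64, overlap 32, nfft 64 — at
128 samples this is 3 averaged segments with 2 Hz bins at fs 128; the DC
bin is excluded and ties break to the lower frequency), configure the
calibrated filter, and iterate it on its own output **zero-phase**
(forward–backward): a single pass rotates phase ≈ 90° at resonance, so
the iterate would never stabilize as a waveform. Each iterate is
renormalized to unit standard deviation, which makes the convergence test
`SD(current − previous) < StDth` (StDth = 0.125) exactly the stated
relative criterion and insensitive to overall filter gain; the cap is 100
inner iterations. The converged iterate fixes the mode's *shape*; its
amplitude is the least-squares projection of the input onto that shape.
The residual is input minus mode, so Σ modes + final residual telescopes
to the input exactly, by construction. The outer loop stops when the
residual keeps less than Pth = 0.2 of the original energy or at the
safety cap (8 modes); the first 3 modes are retained (missing planes are
zero-filled with a logged warning), giving the 256 × 128 × 3 stack per
trial.

Per-channel decomposition is embarrassingly parallel; `decompose_batch`
vectorizes it by grouping channels that share a filter configuration and
is tested to agree with the per-signal path to 1e-9. Fidelity to any
particular reference decomposition code is *functional* (band separation,
reconstruction, determinism), not numerical.

## Channel clustering and image ordering

Lloyd's k-means (k = 19, Euclidean, via scikit-learn with `n_init=1`)
seeded at the anchor coordinates — seeding makes the procedure fully
deterministic, with no restart sensitivity. Raw cluster indices are
relabeled 1–19 by Hungarian matching of cluster centroids to the
canonical anchors (a bijection even if a cluster swallows two anchors,
which average-linkage agglomeration — provided for comparison — does
produce on uniform layouts). Clustering uses straight-line 3-D distances,
not scalp geodesics; at 10–20 scale the two rank-order inter-electrode
distances nearly identically. Row order for the image tensor: groups in
the canonical anchor sequence Fp1 … O2, electrodes within a group by
ascending distance to the group centroid, ties by electrode index —
deterministic because the CNN input must be reproducible. Empty clusters
are repaired by scikit-learn's relocation (reseeding at the
worst-represented points); anchored seeding makes this a near-impossible
code path.

## The network

Single block, in NumPy: 30 filters of 8 × 8 applied identically to each
of the 3 mode planes (weights shared across planes, so the mode dimension
passes through unchanged), ReLU, 3 × 3 max-pooling with stride 2
(floor arithmetic for non-divisible cases), one fully connected softmax
layer (2 or 4 units), cross-entropy loss. For a 256 × 128 input the chain
is 249 × 121 after convolution and 124 × 60 after pooling. Convolution is
im2col + GEMM; pooling is a max-reduce over the nine window offsets, with
gradients routed to the first offset achieving the max (exact ties among
positive activations have measure zero; ties at ReLU zeros are
annihilated by the ReLU mask). All gradients are analytic and are checked
against central finite differences to ~1e-10 relative error in the test
suite.

Training: Adam at learning rate 1e-3, mini-batches of 16, weight
initialization and batch order seeded — two runs with one seed produce
bit-identical weights. Splitting is stratified: 25 % test holdout, the
remaining 75 % divided into 10 stratified folds (90/10 within the
training portion per fold); one model per fold reports validation
accuracy, and the final model is refit on the whole training portion.
Splits are trial-level (subject-level splitting is a caller choice — pass
labels grouped accordingly). Epoch budgets are deliberately small: at the
reference sizes with a strong effect the network separates the classes
within 2–3 epochs, and the desk-scale experiment suites train fold models
for 2 epochs and the final model for 3 (reduced-geometry tests use 6
epochs at 3e-3, as fewer trials and channels give the optimizer fewer,
noisier steps per epoch).

## Metrics

Binary AUC is the rank statistic (Mann-Whitney formulation, midrank
ties); it is held equal to trapezoidal ROC AUC to 1e-10 by test against
scikit-learn's ROC curve. Multiclass: accuracy by argmax (ties toward the
lower class index), macro (unweighted) precision/recall, and AUC as the
unweighted mean of one-vs-rest AUCs — macro averaging is the reading
consistent with reporting a single 5-decimal recall for 4 classes.
Confusion matrices are percentages of the test set. The binary positive
class is `Bul` (the detection target).

Mann-Whitney U is computed from rank sums with midrank ties; p-values are
exact by enumeration of all C(n₁+n₂, n₁) group assignments when both
samples have ≤ 8 observations, and tie-corrected normal approximation
otherwise. The group-power statistic for the gender-style analysis is the
per-subject mean over member channels and trials of Welch total power
(PSD integrated over frequency). No multiple-testing correction is
applied across the 19 groups by default; a Benjamini-Hochberg flag is
available in the analysis script.

## Scenario orchestration

`run_scenario` wires the stages for the four scenarios (Scn1: neither SWD
nor clustering — raw preprocessed trials as a single plane in storage
order; Scn2: clustering only; Scn3: SWD only; Scn4: both). One global
seed fans out to per-stage seeds by fixed offsets; the manifest records
every seed, a config hash, stage shapes and fold metrics, and suffices to
re-execute an identical run. An optional stage cache lets several
scenarios share the simulate/preprocess/SWD stages (results are identical
with or without it); the scenario comparison is therefore paired — same
recordings, same split.

## Problem sizes and what the tests show

The reference experiment (tests and `scripts/acceptance.py`) uses the
session geometry above (238 trials of 256 × 256 → 256 × 128 × 3 tensors)
with `effect_scale = 5` for the power check and `effect_scale = 0` for
the null check; the whole scenario suite runs in roughly ten minutes on
one CPU. Reduced-geometry tests (24 channels, 64 samples, 6 subjects)
exercise wiring, determinism and the monotone response of accuracy to
effect size in seconds per run.

Passing these tests shows that the pipeline recovers band- and
group-localized class differences when they exist, collapses to chance
when they do not, and that clustering-ordered rows do not hurt (and
typically help) generalization relative to arbitrary row order. It does
**not** show that the pipeline discriminates real bullying-related EEG:
the generator has no volume conduction, no artifacts (ocular, muscle,
electrode drift — out of scope by design), no inter-subject variability
in effect topography, and its class effects are stationary narrowband
bursts rather than broadband induced responses. Headline numbers from
real recordings are therefore not reproduction targets here.

## Numerical choices and degenerate inputs

* Welch uses `detrend=False` (the signals are already centered by
  preprocessing); spectra of length-128 inputs use 3 segments.
* A zero signal raises a no-component error before filtering; a filter
  that annihilates its input (zero SD iterate) does likewise rather than
  dividing by zero; a mode orthogonal to the signal (zero projection) is
  treated as no component.
* `Pth` is interpreted as the residual-to-original *energy* ratio
  (the alternative peak-PSD reading has no stable meaning across
  iterations); `StDth` is relative to the current output's SD, so
  convergence is amplitude-invariant.
* Resampling refuses to upsample (trials are only ever shortened).
* The k-means objective is non-increasing per iteration (library
  guarantee); assignment determinism follows from deterministic seeding.
* Float32 is used inside network training for speed; gradient tests run
  the same code in float64.
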