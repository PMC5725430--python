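# swdeeg

Classification of visual-stimulus categories from high-density EEG, built
around three stages: **swarm decomposition** (SWD) of every channel into
band-localized oscillatory modes, **spatial clustering** of the 256
electrodes into the 19 regions of the 10–20 system to arrange trials as
image-like tensors, and a small **convolutional network** that classifies
the result (bullying-related vs neutral stimuli, optionally crossed with
2D vs immersive presentation context).

Recordings of this kind are not publicly distributable, so the package is
driven end to end by a **synthetic HD-EEG generator**: 1/f Gaussian
background plus class-dependent narrowband bursts injected into chosen
anatomical groups, with an exact null mode (`effect_scale = 0`). Every
stage is testable without any download.

## The pipeline

For a trial `x ∈ R^(256×256)` sampled at 250 Hz:

1. **Preprocess** — zero-phase 0.3–30 Hz bandpass; per channel
   `x ← (x − mean x)/max(x − mean x)`; zero-phase 7 Hz highpass;
   polyphase resampling to 128 samples.
2. **SWD** — iteratively: estimate the residual's dominant frequency by
   Welch periodogram (Hann 64, overlap 32, nfft 64), apply a calibrated
   swarm filter — a damped resonator arising from M agents pursuing the
   signal, `v ← (1−1/M)·v + δ(s − x̄)`, `x̄ ← x̄ + v` — repeatedly
   (zero-phase) until the waveform stabilizes
   (`SD(yₖ − yₖ₋₁) < 0.125`, unit-SD iterates), subtract, and repeat
   while the residual keeps ≥ 20 % of the original energy. The first 3
   modes are kept: `256 × 128 × 3` per trial.
3. **Cluster** — k-means (k = 19, Euclidean) seeded at the canonical
   10–20 anchor coordinates; rows reordered group-by-group so
   convolution kernels span anatomically adjacent electrodes.
4. **Classify** — 30 filters of 8×8 shared across the 3 mode planes
   (conv output 249 × 121), ReLU, 3×3/stride-2 max-pool (→ 124 × 60),
   fully connected softmax; cross-entropy, Adam; 25 % stratified test
   holdout and 10-fold cross-validation on the rest.

Metrics: accuracy, precision/recall (positive class `Bul`; macro for 4
classes), rank-statistic AUC (averaged one-vs-rest for 4 classes), and
percentage confusion matrices. A Mann-Whitney U test (exact for small
samples) supports the per-group spectral-power gender analysis.

## Worked example

The numbered scripts under `analysis/` run the study stages; all accept
`--seed` and write their tables under `results/`. A small session first:

```bash
$ python analysis/01_simulate_dataset.py --n-subjects 2 --trials-per-class 2 --out scratch/ds
wrote 8 trials (256 ch x 256 samp) for 2 subjects to scratch/ds
$ python analysis/02_preprocess.py --data scratch/ds --out scratch/pre
preprocessed 8 trials: (256, 256) -> (256, 128) at fs 125.0 Hz; per-channel max 1.52
$ python analysis/03_decompose.py --data scratch/pre --out scratch/ocm
decomposed 8 x 256 channels -> (8, 256, 128, 3); mean residual energy 0.321 of input
$ python analysis/04_cluster_channels.py --out scratch/res
       method  silhouette  min_group_size  max_group_size
       kmeans    0.307942              10              21
agglomerative    0.248041               8              20
-> kmeans gives the tighter grouping on this layout; ...
```

The residual energy (0.32) is what remains after the three retained
modes — pink noise is broadband, so the narrowband modes cannot absorb
everything. The silhouette comparison shows why k-means is the adopted
grouping: tighter, more balanced regions than average-linkage
agglomeration.

The scenario comparison (`analysis/05_run_scenarios.py`, ~15 min on one
CPU: 17 subjects × 14 trials, strong 10 Hz centro-parietal effect,
`effect_scale = 5`) exercises the design question — what do
decomposition and clustering each contribute:

```
$ python analysis/05_run_scenarios.py --seed 42
                  scenario   swd  clustering  test_accuracy  test_auc
 Scn1 (raw, storage order) False       False           0.95       1.0
 Scn3 (SWD, storage order)  True       False           1.00       1.0
   Scn4 (SWD + clustering)  True        True           1.00       1.0
Scn4 null (effect_scale=0)  True        True           0.50       NaN

Scn4 10-fold mean validation accuracy: 0.989
Scn4 precision 1.000 recall 1.000 (test set of 60 trials)
```

The adopted pipeline (Scn4) tops the comparison, and the null row is the
calibration check: with no injected effect the classifier stays at
chance (other seeds leave Scn1 at chance too — the raw single-plane
scenario is the fragile one). `analysis/06_gender_analysis.py` runs the
matching null group-power comparison: no significant group, as expected.

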