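"""Canned experiments: the checks and scenario suites the analysis scripts,
test suite and acceptance script all share.

Problem sizes here are the package's reference desk-scale conditions: the
T1-like session (17 subjects x 14 trials of 256 channels x 256 samples)
with a strong (effect_scale=5) and a null (effect_scale=0) variant, plus
small signal-level checks (reconstruction, two-tone separation, clustering
recovery, metric cross-validation against brute-force oracles).
"""

from __future__ import annotations

import numpy as np

from .clustering import kmeans_groups
from .cnn import CNNConfig
from .evaluation import mann_whitney_u, rank_auc
from .montage import ElectrodeLayout, TEN_TWENTY_NAMES, _anchor_xyz
from .pipeline import ScenarioConfig, run_scenario
from .simulate import SimulationConfig, default_two_class_spec, nearest_anchor_groups
from .swd import SWDParams, dominant_frequency, swd_decompose, welch_psd

__all__ = [
    "scenario_suite",
    "reconstruction_check",
    "twotone_separation_check",
    "clustering_recovery_check",
    "metric_oracle_check",
]


# ---------------------------------------------------------------------------
# full-pipeline scenario suite

def scenario_suite(seed: int = 0, effect_scale: float = 5.0,
                   epochs: int = 3, cv_epochs: int = 2) -> dict:
    """Run Scn4 (with 10-fold CV), Scn3, Scn1 on one strong-effect dataset
    and Scn4 on a matched null dataset; return the headline metrics.

    The scenario comparison is paired: all strong-effect scenarios see the
    same simulated recordings and the same train/test split.
    """
    out: dict = {"seed": seed, "effect_scale": effect_scale}

    def cfg_for(scn: int, effect: float, cv: bool) -> ScenarioConfig:
        sim = SimulationConfig(class_spec=default_two_class_spec(),
                               effect_scale=effect, seed=seed)
        return ScenarioConfig(
            scenario=scn, task=2, sim=sim,
            cnn=CNNConfig(n_classes=2, epochs=epochs, cv_epochs=cv_epochs,
                          seed=seed + 3),
            cross_validate=cv, seed=seed,
        )

    cache: dict = {}  # share simulate/preprocess/SWD across scenarios
    rep4, man4 = run_scenario(cfg_for(4, effect_scale, True), cache)
    out["scn4_val_accuracy"] = man4["validation_accuracy"]
    out["scn4_test_accuracy"] = rep4.accuracy
    out["scn4_test_auc"] = rep4.auc
    out["scn4_precision"] = rep4.precision
    out["scn4_recall"] = rep4.recall
    out["scn4_confusion"] = rep4.confusion.tolist()
    out["scn4_fold_accuracies"] = [
        m["val_accuracy"] for m in man4["stages"]["train"]["fold_metrics"]]
    out["scn4_fold_epoch_accuracies"] = [
        m["val_accuracy_by_epoch"]
        for m in man4["stages"]["train"]["fold_metrics"]]
    n_trials = man4["stages"]["simulate"]["shape"][0]
    out["n_test"] = int(np.ceil(n_trials * 0.25))

    rep3, _ = run_scenario(cfg_for(3, effect_scale, False), cache)
    out["scn3_test_accuracy"] = rep3.accuracy
    out["scn3_test_auc"] = rep3.auc

    rep1, _ = run_scenario(cfg_for(1, effect_scale, False), cache)
    out["scn1_test_accuracy"] = rep1.accuracy
    out["scn1_test_auc"] = rep1.auc

    rep0, _ = run_scenario(cfg_for(4, 0.0, False))
    out["null_test_accuracy"] = rep0.accuracy
    return out


# ---------------------------------------------------------------------------
# SWD checks

def reconstruction_check(n_signals: int = 1000, n_samples: int = 128,
                         seed: int = 0) -> dict:
    """Decompose pink-noise channels; verify sum(OCMs) + residual == input.

    Returns the maximum relative reconstruction error over all signals.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_signals, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    signals = np.fft.irfft(spec * scale, n_samples, axis=1)
    params = SWDParams()
    worst = 0.0
    for x in signals:
        ocms, residual = swd_decompose(x, params)
        recon = np.sum(ocms, axis=0) + residual if ocms else residual
        err = float(np.linalg.norm(recon - x) / np.linalg.norm(x))
        worst = max(worst, err)
    return {"n_signals": n_signals, "max_relative_error": worst}


def _fft_bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.shape[-1], 1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(spec, x.shape[-1])


def twotone_separation_check(n_cases: int = 100, seed: int = 7,
                             fs: float = 128.0, n_samples: int = 128) -> dict:
    """Two-tone oracle: random tone pairs >= 3 Welch bins (6 Hz) apart.

    A case succeeds when the first two OCMs' dominant frequencies match the
    true tones within one Welch bin and each OCM has |r| >= 0.9 with the
    ideal FFT-bandpass component on its side of the spectral valley.
    """
    params = SWDParams()
    bin_hz = fs / params.welch_nfft  # 2 Hz
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    hits = 0
    min_corrs = []
    for _ in range(n_cases):
        while True:
            f1, f2 = np.sort(rng.uniform(8.0, 29.0, size=2))
            if f2 - f1 >= 3 * bin_hz:
                break
        a1, a2 = rng.uniform(0.7, 1.3, size=2)
        x = (a1 * np.sin(2 * np.pi * f1 * t + rng.uniform(0, 2 * np.pi))
             + a2 * np.sin(2 * np.pi * f2 * t + rng.uniform(0, 2 * np.pi)))
        ocms, _ = swd_decompose(x, params)
        if len(ocms) < 2:
            min_corrs.append(0.0)
            continue
        doms = []
        for o in ocms[:2]:
            fr, ps = welch_psd(o, params, fs=fs)
            doms.append(dominant_frequency(fr, ps) * fs / 2.0)
        lo_i = int(np.argmin(doms))
        o_lo, o_hi = ocms[:2][lo_i], ocms[:2][1 - lo_i]
        mid = 0.5 * (f1 + f2)
        comp_lo = _fft_bandpass(x, max(f1 - 3 * bin_hz, 0.5), mid, fs)
        comp_hi = _fft_bandpass(x, mid, f2 + 3 * bin_hz, fs)
        r_lo = abs(np.corrcoef(o_lo, comp_lo)[0, 1])
        r_hi = abs(np.corrcoef(o_hi, comp_hi)[0, 1])
        min_corrs.append(min(r_lo, r_hi))
        freq_ok = (abs(min(doms) - f1) <= bin_hz
                   and abs(max(doms) - f2) <= bin_hz)
        if freq_ok and r_lo >= 0.9 and r_hi >= 0.9:
            hits += 1
    return {"n_cases": n_cases, "hits": hits,
            "median_min_corr": float(np.median(min_corrs))}


# ---------------------------------------------------------------------------
# clustering oracle

def perturbation_layout(n_channels: int, epsilon: float,
                        seed: int) -> ElectrodeLayout:
    """Anchors plus fillers jittered within ``epsilon`` of random anchors."""
    anchors = _anchor_xyz()
    rng = np.random.default_rng(seed)
    n_fill = n_channels - 19
    owner = rng.integers(0, 19, size=n_fill)
    jitter = rng.standard_normal((n_fill, 3))
    jitter *= (epsilon * rng.uniform(0.2, 0.95, n_fill)
               / np.linalg.norm(jitter, axis=1))[:, None]
    coords = np.vstack([anchors, anchors[owner] + jitter])
    labels = list(TEN_TWENTY_NAMES) + [f"E{i+1}" for i in range(n_fill)]
    perm = rng.permutation(n_channels)
    labels = [labels[i] for i in perm]
    return ElectrodeLayout(labels=labels, coords=coords[perm],
                           anchors={n: labels.index(n) for n in TEN_TWENTY_NAMES})


def clustering_recovery_check(n_layouts: int = 20, n_channels: int = 64,
                              seed: int = 0) -> dict:
    """On anchor-perturbation layouts (anchors >= 10 eps apart), k-means must
    equal nearest-anchor assignment; the partition property must hold."""
    anchors = _anchor_xyz()
    d = np.linalg.norm(anchors[:, None] - anchors[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    eps = 0.9 * d.min() / 10.0
    mismatches = 0
    partition_failures = 0
    for i in range(n_layouts):
        layout = perturbation_layout(n_channels, eps, seed + i)
        asg = kmeans_groups(layout)
        oracle = nearest_anchor_groups(layout)
        if not np.array_equal(asg.group_of, oracle):
            mismatches += 1
        sizes = np.bincount(asg.group_of, minlength=20)[1:]
        if np.any(sizes == 0) or sizes.sum() != n_channels:
            partition_failures += 1
    return {"n_layouts": n_layouts, "epsilon": eps,
            "assignment_mismatches": mismatches,
            "partition_failures": partition_failures}


# ---------------------------------------------------------------------------
# metric oracles

def metric_oracle_check(n_instances: int = 100, seed: int = 0) -> dict:
    """Rank AUC vs trapezoidal ROC; Mann-Whitney U vs pairwise counting."""
    from sklearn.metrics import roc_curve

    rng = np.random.default_rng(seed)
    worst_auc_diff = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 2)  # rounding forces ties
        fpr, tpr, _ = roc_curve(y, s)
        trap = float(np.trapezoid(tpr, fpr))
        worst_auc_diff = max(worst_auc_diff, abs(rank_auc(y, s) - trap))

    worst_u_diff = 0.0
    for n1 in range(1, 9):
        for n2 in range(1, 9):
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            u, _ = mann_whitney_u(a, b)
            brute = float(sum(1.0 if x > y else 0.5 if x == y else 0.0
                              for x in a for y in b))
            worst_u_diff = max(worst_u_diff, abs(u - brute))
    return {"max_auc_disagreement": worst_auc_diff,
            "max_u_disagreement": worst_u_diff}
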