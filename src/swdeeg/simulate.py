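"""Synthetic HD-EEG generator.

Emulates the statistical structure the downstream pipeline assumes: a 1/f
(pink) Gaussian background on every channel, plus class-dependent
narrowband oscillatory bursts injected only into the channels of selected
anatomical groups.  Groups are defined generatively as nearest-10-20-anchor
regions of the layout, which is what the spatial clustering stage is meant
to recover.  Everything is reproducible bit-for-bit from the config seed.

An ``effect_scale`` of 0 produces a null dataset in which the class label
carries no information; large values produce easily separable classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import ElectrodeLayout
from .preprocess import TrialTensor

__all__ = [
    "SimulationConfig",
    "LabeledDataset",
    "generate_dataset",
    "nearest_anchor_groups",
    "default_two_class_spec",
    "default_four_class_spec",
    "save_dataset",
    "load_dataset",
]

TWO_CLASS_LABELS = ("Bul", "NoBul")
FOUR_CLASS_LABELS = ("Bul2D", "NoBul2D", "BulVR", "NoBulVR")

#: (group-id, center frequency Hz, amplitude) effects per class.
ClassSpec = dict[str, list[tuple[int, float, float]]]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def default_two_class_spec() -> ClassSpec:
    """Bullying trials carry a 10 Hz (alpha) burst over centro-parietal
    groups C3/Cz/C4 (group ids 9-11); neutral trials are background only."""
    alpha = [(9, 10.0, 1.0), (10, 10.0, 1.0), (11, 10.0, 1.0)]
    return {"Bul": list(alpha), "NoBul": []}

def default_four_class_spec() -> ClassSpec:
    """Crosses the stimulus effect (10 Hz central) with a context effect
    (20 Hz beta over frontal groups Fp1/Fp2) marking the immersive (VR)
    presentations."""
    alpha = [(9, 10.0, 1.0), (10, 10.0, 1.0), (11, 10.0, 1.0)]
    beta = [(1, 20.0, 1.0), (2, 20.0, 1.0)]
    return {
        "Bul2D": list(alpha),
        "NoBul2D": [],
        "BulVR": list(alpha) + list(beta),
        "NoBulVR": list(beta),
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording session.

    Defaults mirror a T1-like session: 17 subjects, 256 channels sampled at
    250 Hz, 256-sample trials, 7 trials per class (14 per subject for the
    2-class design).
    """

    n_subjects: int = 17
    trials_per_class: int = 7
    n_channels: int = 256
    n_samples: int = 256
    fs: float = 250.0
    class_spec: ClassSpec = field(default_factory=default_two_class_spec)
    noise_exponent: float = 1.0
    effect_scale: float = 1.0
    burst_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 19:
            raise ConfigError("n_channels must be >= 19")
        if self.n_subjects < 1 or self.trials_per_class < 1:
            raise ConfigError("n_subjects and trials_per_class must be >= 1")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be >= 0")
        for label, effects in self.class_spec.items():
            for gid, f0, amp in effects:
                if not 1 <= int(gid) <= 19:
                    raise ConfigError(
                        f"class {label!r}: group id {gid} outside [1, 19]"
                    )
                if self.fs <= 2.0 * f0:
                    raise ConfigError(
                        f"class {label!r}: fs={self.fs} too low for {f0} Hz effect"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.class_spec.keys())


@dataclass
class LabeledDataset:
    """Trials with class labels and subject ids (parallel lists)."""

    trials: list[TrialTensor]
    labels: list[str]
    subject_ids: list[int]

    def __post_init__(self) -> None:
        if not (len(self.trials) == len(self.labels) == len(self.subject_ids)):
            raise ConfigError("trials/labels/subject_ids length mismatch")
        n_ch = {t.data.shape[0] for t in self.trials}
        if len(n_ch) > 1:
            raise ConfigError(f"inconsistent channel counts: {sorted(n_ch)}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].data.shape[0]

    def as_array(self) -> np.ndarray:
        """Stack trials into (n_trials, channels, samples)."""
        return np.stack([t.data for t in self.trials])


def nearest_anchor_groups(layout: ElectrodeLayout) -> np.ndarray:
    """Ground-truth group id (1-19) per electrode: nearest 10-20 anchor."""
    anchors = layout.anchor_coords()  # (19, 3) canonical order
    d2 = ((layout.coords[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1) + 1


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit RMS/channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= scale
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt((out**2).mean(axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def generate_dataset(cfg: SimulationConfig, layout: ElectrodeLayout) -> LabeledDataset:
    """Simulate trials for every subject and class.

    Each trial is pink background noise; for its class's (group, f0, amp)
    effects, a Hann-windowed sinusoidal burst of amplitude
    ``amp * effect_scale`` is added to every channel of that group, with
    per-trial random phase (shared across the group, so the oscillation is
    spatially coherent) and onset jittered uniformly over the trial.
    """
    if layout.n_channels != cfg.n_channels:
        raise ConfigError(
            f"layout has {layout.n_channels} channels, config wants {cfg.n_channels}"
        )
    groups = nearest_anchor_groups(layout)
    present = set(np.unique(groups).tolist())
    for label, effects in cfg.class_spec.items():
        for gid, _, _ in effects:
            if int(gid) not in present:
                raise ConfigError(
                    f"class {label!r} references group {gid} absent from layout"
                )

    rng = np.random.default_rng(cfg.seed)
    burst_len = max(8, int(round(cfg.burst_fraction * cfg.n_samples)))
    burst_len = min(burst_len, cfg.n_samples)
    window = np.hanning(burst_len)
    t_burst = np.arange(burst_len) / cfg.fs

    trials: list[TrialTensor] = []
    labels: list[str] = []
    subject_ids: list[int] = []
    for subj in range(cfg.n_subjects):
        for label in cfg.labels:
            effects = cfg.class_spec[label]
            for k in range(cfg.trials_per_class):
                data = _pink_noise(rng, cfg.n_channels, cfg.n_samples,
                                   cfg.noise_exponent)
                for gid, f0, amp in effects:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    onset = rng.integers(0, cfg.n_samples - burst_len + 1)
                    burst = (amp * cfg.effect_scale * window
                             * np.sin(2.0 * np.pi * f0 * t_burst + phase))
                    mask = groups == int(gid)
                    data[mask, onset:onset + burst_len] += burst
                trials.append(TrialTensor(
                    data=data, fs=cfg.fs, subject_id=subj,
                    trial_id=f"S{subj:02d}-{label}-{k:02d}",
                ))
                labels.append(label)
                subject_ids.append(subj)
    return LabeledDataset(trials=trials, labels=labels, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# dataset container: one .npz per subject + JSON manifest; bit-exact round trip

def save_dataset(dataset: LabeledDataset, directory) -> None:
    """Write one ``subject_XX.npz`` (channels x samples x trials) plus a
    ``subject_XX.json`` manifest per subject."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = sorted(set(dataset.subject_ids))
    for subj in subjects:
        idx = [i for i, s in enumerate(dataset.subject_ids) if s == subj]
        arr = np.stack([dataset.trials[i].data for i in idx], axis=2)
        manifest = {
            "subject_id": int(subj),
            "fs": float(dataset.trials[idx[0]].fs),
            "labels": [dataset.labels[i] for i in idx],
            "trial_ids": [dataset.trials[i].trial_id for i in idx],
            "class_map": sorted(set(dataset.labels)),
        }
        np.savez(directory / f"subject_{subj:02d}.npz", data=arr)
        with open(directory / f"subject_{subj:02d}.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def load_dataset(directory) -> LabeledDataset:
    """Inverse of :func:`save_dataset`."""
    directory = Path(directory)
    trials: list[TrialTensor] = []
    labels: list[str] = []
    subject_ids: list[int] = []
    for npz_path in sorted(directory.glob("subject_*.npz")):
        with open(npz_path.with_suffix(".json")) as fh:
            manifest = json.load(fh)
        with np.load(npz_path) as npz:
            arr = npz["data"]
        subj = int(manifest["subject_id"])
        for k in range(arr.shape[2]):
            trials.append(TrialTensor(
                data=arr[:, :, k], fs=float(manifest["fs"]),
                subject_id=subj, trial_id=manifest["trial_ids"][k],
            ))
            labels.append(manifest["labels"][k])
            subject_ids.append(subj)
    return LabeledDataset(trials=trials, labels=labels, subject_ids=subject_ids)
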