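"""Trial preprocessing: bandpass, per-channel normalization, 7 Hz highpass,
and anti-aliased resampling to a fixed trial length.

The default chain (in this order) is

    bandpass 0.3-30 Hz -> normalize -> highpass 7 Hz -> resample to 128

which takes a raw trial (e.g. 256 channels x 256 samples at 250 Hz) to the
256 x 128 representation the swarm decomposition consumes.  The 7 Hz
highpass removes slow content that would dominate the first extracted
oscillatory modes; normalization (subtract mean, divide by the post-centering
maximum) puts every channel on a comparable scale with max exactly 1.

All filters are 4th-order Butterworth applied forward-backward (zero phase);
resampling is rational-factor polyphase (anti-aliased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal

__all__ = [
    "TrialTensor",
    "bandpass_initial",
    "normalize",
    "highpass7",
    "resample_to",
    "subtract_baseline",
    "preprocess_trial",
    "preprocess_dataset_array",
]


class PreprocessError(ValueError):
    """Invalid preprocessing configuration or input."""


class DegenerateChannelWarning(UserWarning):
    """A constant channel was zero-filled during normalization."""


@dataclass
class TrialTensor:
    """One trial's multichannel signal (channels x samples) with metadata."""

    data: np.ndarray
    fs: float
    subject_id: int | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise PreprocessError(
                f"trial data must be channels x samples (>=2), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError("trial data contains non-finite values")

    def replace(self, data: np.ndarray, fs: float | None = None) -> "TrialTensor":
        return TrialTensor(data=data, fs=self.fs if fs is None else fs,
                           subject_id=self.subject_id, trial_id=self.trial_id)


# ---------------------------------------------------------------------------
# array-level stages (operate on any (..., samples) array)

def bandpass_array(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    if not 0.0 < low < high < fs / 2.0:
        raise PreprocessError(
            f"band ({low}, {high}) Hz invalid for fs={fs} (Nyquist {fs / 2})"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def highpass_array(x: np.ndarray, fs: float, cutoff: float = 7.0) -> np.ndarray:
    if fs <= 2.0 * cutoff:
        raise PreprocessError(f"fs={fs} too low for a {cutoff} Hz highpass")
    sos = signal.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def normalize_array(x: np.ndarray) -> np.ndarray:
    """Per channel: subtract the mean, divide by the post-centering maximum.

    Constant channels cannot be normalized; they are zero-filled and
    reported via :class:`DegenerateChannelWarning`.
    """
    centered = x - x.mean(axis=-1, keepdims=True)
    peak = centered.max(axis=-1, keepdims=True)
    degenerate = peak <= 0.0
    if np.any(degenerate):
        n_bad = int(degenerate.sum())
        warnings.warn(
            f"{n_bad} constant channel(s) zero-filled during normalization",
            DegenerateChannelWarning,
            stacklevel=2,
        )
    safe_peak = np.where(degenerate, 1.0, peak)
    out = centered / safe_peak
    return np.where(degenerate, 0.0, out)


def resample_array(x: np.ndarray, n_out: int) -> np.ndarray:
    n_in = x.shape[-1]
    if n_in < n_out:
        raise PreprocessError(f"cannot upsample {n_in} -> {n_out} samples")
    if n_in == n_out:
        return np.array(x, copy=True)
    g = gcd(n_in, n_out)
    up, down = n_out // g, n_in // g
    return signal.resample_poly(x, up, down, axis=-1)


# ---------------------------------------------------------------------------
# TrialTensor-level operations

def bandpass_initial(trial: TrialTensor, low: float = 0.3,
                     high: float = 30.0) -> TrialTensor:
    """Zero-phase 0.3-30 Hz bandpass (acquisition-band emulation)."""
    return trial.replace(bandpass_array(trial.data, trial.fs, low, high))


def normalize(trial: TrialTensor) -> TrialTensor:
    """Per-channel: x <- (x - mean(x)) / max(x - mean(x))."""
    return trial.replace(normalize_array(trial.data))


def highpass7(trial: TrialTensor, cutoff: float = 7.0) -> TrialTensor:
    """Zero-phase highpass; removes slow content that stalls mode extraction."""
    return trial.replace(highpass_array(trial.data, trial.fs, cutoff))


def resample_to(trial: TrialTensor, n_out: int = 128) -> TrialTensor:
    """Polyphase band-limited resampling to exactly ``n_out`` samples."""
    out = resample_array(trial.data, n_out)
    new_fs = trial.fs * n_out / trial.data.shape[-1]
    return trial.replace(out, fs=new_fs)


def subtract_baseline(trial: TrialTensor, n_baseline: int) -> TrialTensor:
    """Subtract the mean of the first ``n_baseline`` samples per channel.

    Not part of the default chain (the synthetic generator emits segmented,
    baseline-free trials); provided for externally recorded data.
    """
    if not 0 < n_baseline <= trial.data.shape[-1]:
        raise PreprocessError("n_baseline outside trial length")
    base = trial.data[..., :n_baseline].mean(axis=-1, keepdims=True)
    return trial.replace(trial.data - base)


def preprocess_trial(trial: TrialTensor, low: float = 0.3, high: float = 30.0,
                     n_out: int = 128) -> TrialTensor:
    """Full default chain: bandpass -> normalize -> highpass 7 Hz -> resample."""
    return resample_to(highpass7(normalize(bandpass_initial(trial, low, high))),
                       n_out)


def preprocess_dataset_array(data: np.ndarray, fs: float, low: float = 0.3,
                             high: float = 30.0, n_out: int = 128) -> np.ndarray:
    """Vectorized default chain over a (trials, channels, samples) stack."""
    x = bandpass_array(data, fs, low, high)
    x = normalize_array(x)
    x = highpass_array(x, fs)
    return resample_array(x, n_out)
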