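"""Preprocess a simulated session: bandpass, normalize, 7 Hz highpass,
resample to 128 samples.

Reads the container written by 01_simulate_dataset.py and writes the
preprocessed trials (channels x 128) back as a matching container.
"""

import argparse
from pathlib import Path

import numpy as np

from swdeeg.preprocess import preprocess_dataset_array
from swdeeg.simulate import LabeledDataset, load_dataset, save_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results/preprocessed"))
    ap.add_argument("--low", type=float, default=0.3)
    ap.add_argument("--high", type=float, default=30.0)
    ap.add_argument("--n-out", type=int, default=128)
    args = ap.parse_args()

    dataset = load_dataset(args.data)
    raw = dataset.as_array()
    fs = dataset.trials[0].fs
    pre = preprocess_dataset_array(raw, fs, low=args.low, high=args.high,
                                   n_out=args.n_out)
    new_fs = fs * args.n_out / raw.shape[-1]
    out_ds = LabeledDataset(
        trials=[t.replace(pre[i], fs=new_fs)
                for i, t in enumerate(dataset.trials)],
        labels=dataset.labels, subject_ids=dataset.subject_ids)
    save_dataset(out_ds, args.out)
    print(f"preprocessed {raw.shape[0]} trials: {raw.shape[1:]} -> "
          f"{pre.shape[1:]} at fs {new_fs:.1f} Hz; "
          f"per-channel max {np.abs(pre).max():.2f}")


if __name__ == "__main__":
    main()
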