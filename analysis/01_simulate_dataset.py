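"""Generate the reference synthetic HD-EEG session and write it to disk.

Produces a T1-like recording session (17 subjects x 14 trials of
256 channels x 256 samples at 250 Hz) with the default 2-class effect
(10 Hz centro-parietal bursts in bullying trials), plus the electrode
montage, under results/dataset/.
"""

import argparse
import json
from pathlib import Path

from swdeeg.montage import generate_layout, write_sfp
from swdeeg.simulate import SimulationConfig, generate_dataset, save_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--effect-scale", type=float, default=1.0)
    ap.add_argument("--n-subjects", type=int, default=17)
    ap.add_argument("--trials-per-class", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/dataset"))
    args = ap.parse_args()

    cfg = SimulationConfig(n_subjects=args.n_subjects,
                           trials_per_class=args.trials_per_class,
                           effect_scale=args.effect_scale, seed=args.seed)
    layout = generate_layout(cfg.n_channels, seed=args.seed + 1)
    dataset = generate_dataset(cfg, layout)

    args.out.mkdir(parents=True, exist_ok=True)
    save_dataset(dataset, args.out)
    write_sfp(layout, args.out / "montage.sfp")
    with open(args.out / "config.json", "w") as fh:
        json.dump({k: v for k, v in vars(cfg).items() if k != "class_spec"},
                  fh, indent=1)
    print(f"wrote {len(dataset)} trials "
          f"({dataset.n_channels} ch x {dataset.trials[0].data.shape[1]} samp) "
          f"for {args.n_subjects} subjects to {args.out}")


if __name__ == "__main__":
    main()
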