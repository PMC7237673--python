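"""Preprocess raw trials into activation matrices and summarise distributions.

Band-pass 30-400 Hz, rectify, low-pass 6 Hz, crop to the gait cycle,
time-normalise to 200 points, peak-normalise per muscle.  Writes one
activation CSV per trial under results/activations/ and a per-condition
distribution summary (pooled excess kurtosis and skewness of raw signals
and activation matrices) to results/distribution_summary.csv — the
simulated analogue of the raw-EMG distribution table: kurtosis should fall
from walking to fast running while skewness stays near zero.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import emgsynergy as es
from emgsynergy import io as eio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trials", type=Path, default=Path("results/trials"))
    parser.add_argument("--out", type=Path, default=Path("results/activations"))
    parser.add_argument("--cutoff", type=float, default=6.0,
                        help="envelope low-pass cut-off, Hz")
    args = parser.parse_args()

    manifest = json.loads((args.trials / "manifest.json").read_text())
    rows = []
    for entry in manifest["trials"]:
        raw = eio.read_trial(args.trials / entry["stem"])
        act = es.process_trial(raw, envelope_cutoff_hz=args.cutoff)
        eio.write_activation(act, args.out / f"{entry['stem']}.csv")
        raw_sum = es.summarise_distribution(raw.signal.ravel())
        act_sum = es.summarise_distribution(act.x.ravel())
        rows.append({
            "stem": entry["stem"], "condition": entry["condition"],
            "raw_kurtosis": raw_sum.excess_kurtosis, "raw_skewness": raw_sum.skewness,
            "act_kurtosis": act_sum.excess_kurtosis, "act_skewness": act_sum.skewness,
        })

    df = pd.DataFrame(rows)
    df.to_csv(args.out.parent / "distribution_summary.csv", index=False)
    table = df.groupby("condition")[["raw_kurtosis", "raw_skewness"]].agg(["mean", "std"])
    order = [c for c in es.SPEED_CONDITIONS if c in table.index]
    print("pooled raw-EMG distribution by condition:")
    print(table.loc[order].round(3))
    print(f"\nwrote {len(rows)} activation matrices to {args.out}")


if __name__ == "__main__":
    main()
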