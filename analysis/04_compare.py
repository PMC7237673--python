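"""Compare primitive and activation distributions with the KS machinery.

For every trial x method decomposition, computes the all-pairs two-sample
KS statistics between each excitation primitive and each muscle activation
pattern, reducing to the occurrence of agreement (percentage of pairs where
the test fails to reject equality at p < 0.05) and the maximum dissimilarity
index D.  Merges with the VAF table into results/scores.csv (long format)
and writes the all-pairs table to results/ks_pairs.csv.
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
    parser.add_argument("--activations", type=Path, default=Path("results/activations"))
    parser.add_argument("--decompositions", type=Path, default=Path("results/decompositions"))
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--out", type=Path, default=Path("results/scores.csv"))
    args = parser.parse_args()

    manifest = json.loads((args.trials / "manifest.json").read_text())
    vaf_df = pd.read_csv(args.decompositions.parent / "vaf.csv")

    score_rows, pair_rows = [], []
    for e in manifest["trials"]:
        act = eio.read_activation(args.activations / f"{e['stem']}.csv")
        for method in es.METHODS:
            dec = eio.read_decomposition(args.decompositions / e["stem"] / method)
            comp = es.compare_primitives_to_activations(act, dec, alpha=args.alpha)
            score_rows.append({"stem": e["stem"], "method": method,
                               "agreement_pct": comp.agreement_pct,
                               "d_max": comp.D_max})
            for l in range(comp.D_lk.shape[0]):
                for k in range(comp.D_lk.shape[1]):
                    pair_rows.append({"trial": e["stem"], "method": method,
                                      "muscle": act.channel_labels[l],
                                      "primitive": k + 1,
                                      "D": comp.D_lk[l, k], "p": comp.p_lk[l, k]})

    scores = vaf_df.merge(pd.DataFrame(score_rows), on=["stem", "method"])
    scores.to_csv(args.out, index=False)
    pd.DataFrame(pair_rows).to_csv(args.out.parent / "ks_pairs.csv", index=False)
    print("mean scores by method:")
    print(scores.groupby("method")[["vaf", "agreement_pct", "d_max"]].mean().round(3))


if __name__ == "__main__":
    main()
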