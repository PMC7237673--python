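"""Select the number of synergies and factorise every trial.

Runs the VAF-threshold rule (smallest K in 2..6 with VAF > 85% for all four
methods, evaluated on a few representative trials) and then fits NMF, PCA,
ICA and FA at that K to every activation matrix.  Decompositions are written
under results/decompositions/<trial>/<method>/ and per-trial VAF values to
results/vaf.csv.
"""

import argparse
import json
import warnings
from collections import Counter
from pathlib import Path

import pandas as pd

import emgsynergy as es
from emgsynergy import io as eio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trials", type=Path, default=Path("results/trials"))
    parser.add_argument("--activations", type=Path, default=Path("results/activations"))
    parser.add_argument("--out", type=Path, default=Path("results/decompositions"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--k", type=int, default=None,
                        help="fix K instead of selecting it")
    args = parser.parse_args()

    manifest = json.loads((args.trials / "manifest.json").read_text())
    entries = manifest["trials"]
    acts = {e["stem"]: eio.read_activation(args.activations / f"{e['stem']}.csv")
            for e in entries}

    if args.k is None:
        # majority vote over one trial per condition
        per_cond = {}
        for e in entries:
            per_cond.setdefault(e["condition"], e["stem"])
        votes = [es.select_num_synergies(acts[stem], seed=args.seed)
                 for stem in per_cond.values()]
        K = Counter(votes).most_common(1)[0][0]
        print(f"selected K={K} (votes per condition: {dict(zip(per_cond, votes))})")
    else:
        K = args.k
        print(f"using fixed K={K}")

    rows = []
    for e in entries:
        act = acts[e["stem"]]
        for method in es.METHODS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                dec = es.fit_method(act, method, K, seed=e["seed"])
            eio.write_decomposition(dec, args.out / e["stem"] / method)
            rows.append({"stem": e["stem"], "condition": e["condition"],
                         "subject": e["subject"], "method": method, "K": K,
                         "vaf": es.vaf(act, dec.x_hat)})

    df = pd.DataFrame(rows)
    df.to_csv(args.out.parent / "vaf.csv", index=False)
    print("mean VAF by method:")
    print(df.groupby("method")["vaf"].mean().round(4))


if __name__ == "__main__":
    main()
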