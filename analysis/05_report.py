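"""Group statistics and the method-comparison figure.

Runs the one-way repeated-measures ANOVA across factorisation methods per
condition (subjects as the repeated factor, trials averaged to subject
means) with Bonferroni-corrected paired comparisons, for each of the three
metrics (VAF, occurrence of agreement, maximum dissimilarity).  Writes
results/anova.json and the bar-summary figure results/method_comparison.svg.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import emgsynergy as es
from emgsynergy.pipeline import plot_method_comparison


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scores", type=Path, default=Path("results/scores.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    df = pd.read_csv(args.scores)
    anova = {metric: es.group_comparison(df, metric)
             for metric in ("vaf", "agreement_pct", "d_max")}
    (args.out / "anova.json").write_text(json.dumps(anova, indent=2))
    plot_method_comparison(df, args.out / "method_comparison.svg")

    for metric, res in anova.items():
        print(f"\n{metric}: RM-ANOVA across methods")
        for cond, r in res.items():
            sig = " *" if r["p"] < 0.05 else ""
            print(f"  {cond:13s} F({r['df_num']:.0f},{r['df_den']:.0f}) = "
                  f"{r['F']:.2f}, p = {r['p']:.4g}{sig}")
    print(f"\nwrote {args.out / 'anova.json'} and method_comparison.svg")


if __name__ == "__main__":
    main()
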