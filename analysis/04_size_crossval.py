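#!/usr/bin/env python
"""Effect of training-population size, and the PLS component grid.

Random training sets of 50-400 plots (SIZE strategy, replicated draws) are
used to predict the held-out complement with both predictors; PLS is run
at every component count in {5, 10, 20, 50}. Expected pattern: accuracy
rises with training size; the kernel model overtakes PLS once the
training set is no longer tiny; mid-grid component counts beat 50. Writes
results/size_accuracy.tsv and a accuracy-vs-size figure.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from maltpred import (
    MBLUPPredictor,
    PLSRPredictor,
    build_similarity,
    make_folds,
    run_cv,
)
from maltpred.io import read_phenotype_table, read_standardized_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--standardized", type=Path,
                    default=Path("results/preprocessed/standardized.tsv"))
    ap.add_argument("--phenotypes", type=Path,
                    default=Path("results/synthetic/phenotypes.tsv"))
    ap.add_argument("--tp-sizes", default="50,100,200,400")
    ap.add_argument("--replicates", type=int, default=15)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--traits", default=None, help="comma-separated subset")
    ap.add_argument("--out", type=Path, default=Path("results/size_accuracy.tsv"))
    args = ap.parse_args()

    Q = read_standardized_table(args.standardized)
    meta, pheno = read_phenotype_table(args.phenotypes, spectra_ids=Q.plot_ids)
    pheno = pheno.set_index("plot_id").loc[Q.plot_ids]
    K = build_similarity(Q)
    traits = args.traits.split(",") if args.traits else list(pheno.columns)
    sizes = [int(s) for s in args.tp_sizes.split(",")]

    predictors = [MBLUPPredictor(K)] + [
        PLSRPredictor(Q, n_components=k) for k in (5, 10, 20, 50)
    ]
    rows = []
    for tp in sizes:
        folds = make_folds("SIZE", meta, tp_size=tp, n_replicates=args.replicates,
                           seed=args.seed)
        for pred in predictors:
            for trait in traits:
                res = run_cv(pheno[trait], meta, folds, pred)
                rows.append({
                    "strategy": "SIZE", "tp_size": tp, "predictor": pred.name,
                    "trait": trait, "mean": res.replicate_mean,
                    "sd": res.replicate_sd,
                })
        print(f"tp_size={tp} done")
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False, float_format="%.6g")

    wide = table.pivot_table(index=["predictor"], columns="tp_size", values="mean")
    print("\nmean plot-level accuracy (averaged over traits):")
    print(wide.round(3).to_string())

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for name, grp in table.groupby("predictor"):
            curve = grp.groupby("tp_size")["mean"].mean()
            ax.errorbar(curve.index, curve.values, fmt="o-", label=name)
        ax.set_xlabel("training population size")
        ax.set_ylabel("prediction accuracy (Pearson r)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(args.out.with_suffix(".png"), dpi=120)
        print(f"figure written to {args.out.with_suffix('.png')}")
    except ImportError:
        print("matplotlib unavailable; skipping the figure")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
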