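#!/usr/bin/env python
"""Prediction of new lines (LINE) and across locations (LOC).

LINE leaves out every plot of one line per fold (one fold per line) and
pools predictions over folds before correlating — the accuracy of
predicting an unseen genotype. LOC holds out one entire location, the
accuracy of predicting a new environment. Both the kernel BLUP and the
20-component PLS model run on identical folds. Writes
results/line_loc_accuracy.tsv.
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
    ap.add_argument("--traits", default=None, help="comma-separated subset")
    ap.add_argument("--n-components", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/line_loc_accuracy.tsv"))
    args = ap.parse_args()

    Q = read_standardized_table(args.standardized)
    meta, pheno = read_phenotype_table(args.phenotypes, spectra_ids=Q.plot_ids)
    pheno = pheno.set_index("plot_id").loc[Q.plot_ids]
    K = build_similarity(Q)
    traits = args.traits.split(",") if args.traits else list(pheno.columns)
    predictors = [MBLUPPredictor(K), PLSRPredictor(Q, n_components=args.n_components)]

    rows = []
    for strategy in ("LINE", "LOC"):
        folds = make_folds(strategy, meta)
        for pred in predictors:
            for trait in traits:
                res = run_cv(pheno[trait], meta, folds, pred)
                rows.append({
                    "strategy": strategy, "predictor": pred.name, "trait": trait,
                    "accuracy_plot": res.pooled_plot_accuracy,
                    "accuracy_line_mean": res.pooled_line_mean_accuracy,
                    "n_failed_folds": len(res.failed_folds),
                })
            print(f"{strategy} / {pred.name} done")
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False, float_format="%.6g")
    print("\npooled accuracies:")
    print(table.round(3).to_string(index=False))
    print(f"\ntable written to {args.out}")


if __name__ == "__main__":
    main()
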