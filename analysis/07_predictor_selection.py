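#!/usr/bin/env python
"""Select predictors of post-pubertal social-interaction scores from P12
call metrics and gene expression, separately per genotype x session:
Lasso over a penalty path with AICc model choice, validated by 5-repeat
subsample stability and per-gene correlations.

Reads results/{sequences,cohort}; writes selected features, stability
counts and correlations under results/selection/.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocalpredict.expression import compute_rq, rq_wide
from vocalpredict.io import read_call_table
from vocalpredict.selection import (build_feature_matrix,
                                    correlation_validation, lasso_aic,
                                    stability_selection)
from vocalpredict.transitions import pup_feature_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    seg = read_call_table(args.out / "sequences" / "segmented_calls.csv")
    feats = pup_feature_table(seg)
    genes = rq_wide(compute_rq(
        pd.read_csv(args.out / "cohort" / "expression_ct.csv")))
    scores = pd.read_csv(args.out / "cohort" / "social_scores.csv")
    gene_names = [c for c in genes.columns if c not in ("mouse_id", "genotype")]

    out = args.out / "selection"
    out.mkdir(parents=True, exist_ok=True)
    for genotype in ("WT", "Dup"):
        for session in (1, 2):
            X, y = build_feature_matrix(feats, genes, scores, genotype, session)
            res = lasso_aic(X, y)
            counts, _ = stability_selection(X, y, seed=args.seed)
            corr = correlation_validation(X, y, features=gene_names)
            stem = f"{genotype}_s{session}"
            pd.DataFrame({"alpha": res.alphas, "df": res.df, "r2": res.r2,
                          "criterion": res.criterion}) \
                .to_csv(out / f"{stem}_path.csv", index=False)
            res.selected.rename("coefficient") \
                .to_csv(out / f"{stem}_selected.csv")
            counts[counts > 0].rename("n_of_5") \
                .to_csv(out / f"{stem}_stability.csv")
            corr.to_csv(out / f"{stem}_gene_correlations.csv", index=False)
            stable = counts[counts >= 3].index.tolist()
            print(f"{genotype} session {session}: "
                  f"{len(res.selected)} selected "
                  f"(R2={res.r2[res.chosen_index]:.2f}); stable (>=3/5): "
                  f"{stable or 'none'}")


if __name__ == "__main__":
    main()
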