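#!/usr/bin/env python
"""Quantify prefrontal-cortex gene expression (delta-delta-Ct RQ) and test
genotype differences in level and variance.

Reads results/cohort/expression_ct.csv; writes the RQ table and per-gene
statistics under results/expression/.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocalpredict.expression import compute_rq, genotype_tests
from vocalpredict.io import write_results


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ct = pd.read_csv(args.out / "cohort" / "expression_ct.csv")
    rq = compute_rq(ct)
    stats = genotype_tests(rq)

    means = rq.groupby(["gene", "genotype"])["rq"].mean().unstack().round(2)
    print("mean RQ per gene (WT calibrated to 1):")
    print(means.to_string())
    elevated = stats.loc[stats["mwu_sig_fdr5"], "gene"].tolist()
    variable = stats.loc[stats["levene_sig_fdr5"].fillna(False), "gene"].tolist()
    print(f"elevated in Dup after BH(5%): {elevated}")
    print(f"larger Dup variance after BH(5%): {variable}")

    write_results({"rq": rq, "genotype_tests": stats},
                  args.out / "expression", seed=args.seed)


if __name__ == "__main__":
    main()
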