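#!/usr/bin/env python
"""Two-call connection structure: pooled Markov models per genotype x age
with chance-multiple tiers, and the representative pup of each group.

Reads results/sequences/segmented_calls.csv; writes count / proportion /
Markov / tier matrices and representative-pup picks under
results/transitions/.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocalpredict.io import read_call_table
from vocalpredict.transitions import (pup_feature_table, select_representative,
                                      tier_frame, transition_model)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    seg = read_call_table(args.out / "sequences" / "segmented_calls.csv")
    out = args.out / "transitions"
    out.mkdir(parents=True, exist_ok=True)

    feats = pup_feature_table(seg)
    reps = []
    for (geno, age), grp in seg.groupby(["genotype", "age_day"]):
        model = transition_model(grp)
        tiers = tier_frame(model)
        stem = f"{geno}_P{age}"
        model.as_frame("counts").to_csv(out / f"{stem}_counts.csv")
        model.as_frame("proportions").to_csv(out / f"{stem}_proportions.csv")
        model.as_frame("markov").to_csv(out / f"{stem}_markov.csv")
        tiers.to_csv(out / f"{stem}_tiers.csv")
        n_salient = int((tiers != "none").to_numpy().sum())
        diag = float(pd.Series(model.markov.diagonal()).mean())
        group_feats = feats[(feats.genotype == geno) & (feats.age_day == age)]
        rep = select_representative(group_feats.drop(columns=["genotype",
                                                              "age_day"]))
        reps.append({"genotype": geno, "age_day": age, "representative": rep})
        print(f"{geno} P{age}: {model.counts.sum()} connections, "
              f"{n_salient} above-chance cells, mean self-transition "
              f"{diag:.3f}, representative pup {rep}")
    pd.DataFrame(reps).to_csv(out / "representatives.csv", index=False)


if __name__ == "__main__":
    main()
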