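#!/usr/bin/env python
"""Generate the study cohort: 29 +/+ and 25 Dup/+ pups recorded at P8 and
P12, with linked qRT-PCR and social-interaction tables.

Writes results/cohort/{calls.csv, expression_ct.csv, social_scores.csv,
truth.json}.
"""

import argparse
import json
from pathlib import Path

from vocalpredict.io import write_call_table
from vocalpredict.simulate import CohortConfig, simulate_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(CohortConfig(), seed=args.seed)
    write_call_table(cohort["calls"], out / "calls.csv")
    cohort["expression"].to_csv(out / "expression_ct.csv", index=False)
    cohort["scores"].to_csv(out / "social_scores.csv", index=False)
    (out / "truth.json").write_text(json.dumps(cohort["truth"], indent=2))

    calls = cohort["calls"]
    per = calls.groupby(["genotype", "age_day"]).size()
    print(f"cohort written to {out}")
    print(f"  {calls['pup_id'].nunique()} mice, "
          f"{calls.groupby(['pup_id', 'age_day']).ngroups} sessions, "
          f"{len(calls)} calls")
    for (g, a), n in per.items():
        print(f"  {g} P{a}: {n} calls")


if __name__ == "__main__":
    main()
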