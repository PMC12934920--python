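#!/usr/bin/env python
"""Embed the quantitative acoustic features of calls with UMAP, cluster
the embedding, and summarize cluster composition and cluster-level
sequence trajectories per genotype.

Reads results/sequences/segmented_calls.csv; writes embedded coordinates,
cluster composition and trajectory matrices under results/embedding/.
A subsample of calls keeps the embedding tractable.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from vocalpredict.embedding import cluster_composition, embed_calls
from vocalpredict.io import read_call_table
from vocalpredict.transitions import cluster_trajectories


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-calls", type=int, default=4000)
    args = ap.parse_args()

    seg = read_call_table(args.out / "sequences" / "segmented_calls.csv")
    sub = seg.sample(min(args.n_calls, len(seg)), random_state=args.seed) \
        .sort_index()
    res = embed_calls(sub, seed=args.seed)
    print(f"embedded {len(sub)} calls -> {res.n_clusters} clusters "
          f"({(res.cluster_labels == -1).mean():.1%} noise)")

    comp, counts = cluster_composition(sub, res.cluster_labels)
    for cl, grp in comp.groupby("cluster"):
        if cl < 0:
            continue
        top = grp.nlargest(3, "proportion")
        desc = ", ".join(f"{r.call_type} {r.proportion:.0%}"
                         for r in top.itertuples())
        print(f"  cluster {cl}: {desc}")

    out = args.out / "embedding"
    out.mkdir(parents=True, exist_ok=True)
    coords = sub[["pup_id", "genotype", "age_day", "call_type"]].copy()
    coords["umap_x"] = res.coords[:, 0]
    coords["umap_y"] = res.coords[:, 1]
    coords["cluster"] = res.cluster_labels
    coords.to_csv(out / "embedded_calls.csv", index=False)
    comp.to_csv(out / "cluster_composition.csv", index=False)
    counts.to_csv(out / "cluster_counts.csv", index=False)

    # cluster-level trajectories on the full table, using the generator's
    # latent cluster labels carried by the synthetic cohort
    if "acoustic_cluster_truth" in seg.columns:
        rows = []
        for geno, grp in seg.groupby("genotype"):
            M = np.zeros((4, 4), int)
            for _, sess in grp.groupby(["pup_id", "age_day"]):
                M += cluster_trajectories(
                    sess["acoustic_cluster_truth"].to_numpy(int),
                    sess["sequence_id"].to_numpy(), 4)
            within = np.trace(M) / M.sum()
            print(f"  {geno}: within-cluster transition share {within:.2f}")
            for i in range(4):
                for j in range(4):
                    rows.append({"genotype": geno, "from": i, "to": j,
                                 "n": int(M[i, j])})
        pd.DataFrame(rows).to_csv(out / "cluster_trajectories.csv", index=False)


if __name__ == "__main__":
    main()
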