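"""UMAP embedding and density clustering of per-call acoustic features.

Seven quantitative features per call — bandwidth, max/mean/min frequency,
max/mean/min intensity — are z-scored column-wise (Hz and dB are
incommensurate) and embedded with UMAP.  Clusters in the embedding are
found with HDBSCAN; noise labels (-1) are permitted.  K-means with
silhouette-selected k is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ACOUSTIC_FEATURES = [
    "bandwidth_hz", "freq_max_hz", "freq_mean_hz", "freq_min_hz",
    "intensity_max_db", "intensity_mean_db", "intensity_min_db",
]


@dataclass
class EmbeddingResult:
    coords: np.ndarray          # n x 2 (or 3)
    cluster_labels: np.ndarray  # -1 = noise
    n_clusters: int


def embed_calls(features: pd.DataFrame, n_neighbors: int = 15,
                min_dist: float = 0.1, n_components: int = 2,
                seed: int = 0, clusterer: str = "hdbscan",
                min_cluster_size: int | None = None,
                allow_single_cluster: bool = False,
                kmeans_k_range: tuple[int, int] = (2, 8)) -> EmbeddingResult:
    """Embed the acoustic feature table and cluster the embedding.

    Deterministic for a fixed seed.  ``min_cluster_size`` defaults to 2%
    of the number of calls (at least 10).
    """
    import umap
    from sklearn.preprocessing import StandardScaler

    X = features[ACOUSTIC_FEATURES].to_numpy(float)
    if len(X) < n_neighbors:
        raise ValueError(
            f"need at least n_neighbors={n_neighbors} calls, got {len(X)}")
    Xz = StandardScaler().fit_transform(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                            n_components=n_components, random_state=seed)
        coords = reducer.fit_transform(Xz)

    if clusterer == "hdbscan":
        from sklearn.cluster import HDBSCAN
        mcs = min_cluster_size or max(10, len(X) // 50)
        labels = HDBSCAN(min_cluster_size=mcs, copy=True,
                         allow_single_cluster=allow_single_cluster,
                         ).fit_predict(coords)
    elif clusterer == "kmeans":
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score
        best, best_score = None, -np.inf
        for k in range(kmeans_k_range[0], kmeans_k_range[1] + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
            score = silhouette_score(coords, km.labels_)
            if score > best_score:
                best, best_score = km.labels_, score
        labels = best
    else:
        raise ValueError(f"unknown clusterer {clusterer!r}")
    n_clusters = int(len(set(labels)) - (1 if -1 in labels else 0))
    return EmbeddingResult(coords=np.asarray(coords),
                           cluster_labels=np.asarray(labels),
                           n_clusters=n_clusters)


def cluster_composition(df: pd.DataFrame, cluster_labels: np.ndarray,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call-type composition per cluster and cluster counts per group.

    Returns ``(composition, group_counts)``: composition has one row per
    (cluster, call_type) with the type's proportion within the cluster
    (each cluster's proportions sum to 1); group_counts has per
    genotype x age x cluster call counts.  Noise calls (label -1) are
    reported as cluster -1.
    """
    work = df.copy()
    work["cluster"] = np.asarray(cluster_labels)
    comp_rows = []
    for cl, grp in work.groupby("cluster"):
        props = grp["call_type"].value_counts(normalize=True)
        for t, p in props.items():
            comp_rows.append({"cluster": cl, "call_type": t,
                              "proportion": float(p), "n": int(len(grp))})
    counts = (work.groupby(["genotype", "age_day", "cluster"])
              .size().rename("n_calls").reset_index())
    return pd.DataFrame(comp_rows), counts
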