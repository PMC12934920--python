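"""Two-call connections, Markov transition models and tier annotations.

Only within-sequence adjacent call pairs count as connections.  From the
13x13 count matrix C the model derives the connection-proportion matrix
Q = C / sum(C) and the first-order Markov matrix P with rows normalized
(the probability of the next call type conditioned only on the current
one).  Cells of P are annotated with chance-multiple tiers: with K = 13
types the chance level is 1/K, and a cell earns the highest tier m among
the configured multipliers with P > m/K (strictly).  With multipliers
1.5 / 2.0 / 2.5 the thresholds print as 0.1154, 0.1538 and 0.1923.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ALPHABET, ConfigError, tier_thresholds

TIER_NAMES = ("none", "grey", "light_brown", "dark_brown")


class EmptyModelError(ValueError):
    """No two-call connection exists in the input."""


@dataclass
class TransitionModel:
    alphabet: tuple[str, ...]
    counts: np.ndarray                       # KxK int
    proportions: np.ndarray = field(init=False)   # Q, sums to 1
    markov: np.ndarray = field(init=False)        # P, rows sum to 1 or 0
    row_empty: np.ndarray = field(init=False)     # rows with no outgoing pair

    def __post_init__(self) -> None:
        C = np.asarray(self.counts, dtype=float)
        total = C.sum()
        if total == 0:
            raise EmptyModelError("no two-call connections")
        self.proportions = C / total
        row_sums = C.sum(axis=1)
        self.row_empty = row_sums == 0
        safe = np.where(self.row_empty, 1.0, row_sums)
        self.markov = C / safe[:, None]

    def as_frame(self, which: str) -> pd.DataFrame:
        mat = {"counts": self.counts, "proportions": self.proportions,
               "markov": self.markov}[which]
        return pd.DataFrame(mat, index=list(self.alphabet),
                            columns=list(self.alphabet))


def transition_counts(types: np.ndarray, sequence_ids: np.ndarray,
                      alphabet: tuple[str, ...] = ALPHABET) -> np.ndarray:
    """KxK within-sequence adjacent-pair counts."""
    idx = {t: i for i, t in enumerate(alphabet)}
    K = len(alphabet)
    C = np.zeros((K, K), dtype=int)
    types = np.asarray(types)
    sequence_ids = np.asarray(sequence_ids)
    same_seq = sequence_ids[1:] == sequence_ids[:-1]
    for a, b in zip(types[:-1][same_seq], types[1:][same_seq]):
        C[idx[a], idx[b]] += 1
    return C


def transition_model(df: pd.DataFrame,
                     alphabet: tuple[str, ...] = ALPHABET) -> TransitionModel:
    """Pooled transition model over a segmented, labeled call table.

    Pairs never cross session boundaries (each session's sequences are
    independent).
    """
    K = len(alphabet)
    C = np.zeros((K, K), dtype=int)
    for _, grp in df.groupby(["pup_id", "age_day"], sort=False):
        C += transition_counts(grp["call_type"].to_numpy(),
                               grp["sequence_id"].to_numpy(), alphabet)
    return TransitionModel(alphabet=alphabet, counts=C)


def assign_tiers(model: TransitionModel,
                 multipliers: tuple[float, ...] = (1.5, 2.0, 2.5),
                 n_types: int | None = None) -> np.ndarray:
    """Tier index per cell: 0 none, then 1..len(multipliers) ascending.

    A cell gets the highest tier whose threshold m/K it strictly exceeds;
    a cell exactly at chance level (1/K) gets tier 0.
    """
    K = n_types if n_types is not None else len(model.alphabet)
    if K <= 0:
        raise ConfigError("number of call types must be positive")
    taus = tier_thresholds(multipliers, K)
    P = model.markov
    tiers = np.zeros(P.shape, dtype=int)
    for level, tau in enumerate(sorted(taus), start=1):
        tiers[P > tau] = level
    return tiers


def tier_frame(model: TransitionModel,
               multipliers: tuple[float, ...] = (1.5, 2.0, 2.5)) -> pd.DataFrame:
    tiers = assign_tiers(model, multipliers)
    names = np.array(TIER_NAMES[:len(multipliers) + 1])
    return pd.DataFrame(names[tiers], index=list(model.alphabet),
                        columns=list(model.alphabet))


# ---------------------------------------------------------------------------
# Per-pup feature vectors

def feature_names(alphabet: tuple[str, ...] = ALPHABET) -> list[str]:
    """The 533 call-metric feature names: 13 N + 13 P + 169 pair N + 169
    pair P + 169 MP, in a fixed order."""
    names = [f"{t}(N)" for t in alphabet] + [f"{t}(P)" for t in alphabet]
    pairs = [(a, b) for a in alphabet for b in alphabet]
    names += [f"{a}_{b}(N)" for a, b in pairs]
    names += [f"{a}_{b}(P)" for a, b in pairs]
    names += [f"{a}_{b}(MP)" for a, b in pairs]
    return names


def pup_features(types: np.ndarray, sequence_ids: np.ndarray,
                 alphabet: tuple[str, ...] = ALPHABET) -> pd.Series:
    """Named feature vector for one pup session.

    Counts and proportions of call types, counts and proportions of
    two-call connections, and Markov probabilities.  Absent pairs get 0
    for N/P; Markov probabilities from empty rows (the pup never emitted
    the first type within a sequence pair) are NaN, i.e. flagged missing.
    """
    types = np.asarray(types)
    n = len(types)
    vals: dict[str, float] = {}
    counts = pd.Series(types).value_counts()
    for t in alphabet:
        c = int(counts.get(t, 0))
        vals[f"{t}(N)"] = c
        vals[f"{t}(P)"] = c / n if n else np.nan
    C = transition_counts(types, sequence_ids, alphabet)
    total = C.sum()
    rows = C.sum(axis=1)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            vals[f"{a}_{b}(N)"] = int(C[i, j])
            vals[f"{a}_{b}(P)"] = C[i, j] / total if total else 0.0
            vals[f"{a}_{b}(MP)"] = C[i, j] / rows[i] if rows[i] else np.nan
    return pd.Series(vals).reindex(feature_names(alphabet))


def pup_feature_table(df: pd.DataFrame,
                      alphabet: tuple[str, ...] = ALPHABET) -> pd.DataFrame:
    """Feature vectors for every pup x age in a segmented, labeled table."""
    rows = {}
    meta = []
    for (pup, geno, age), grp in df.groupby(["pup_id", "genotype", "age_day"],
                                            sort=True):
        rows[(pup, age)] = pup_features(grp["call_type"].to_numpy(),
                                        grp["sequence_id"].to_numpy(), alphabet)
        meta.append({"pup_id": pup, "genotype": geno, "age_day": age})
    out = pd.DataFrame(rows).T
    out.index.names = ["pup_id", "age_day"]
    out = out.reset_index()
    out.insert(1, "genotype", [m["genotype"] for m in meta])
    return out


# ---------------------------------------------------------------------------
# Representative pup

FEATURE_BLOCKS = ("type_counts", "type_proportions", "pair_counts",
                  "pair_proportions")


def _block_columns(block: str, alphabet: tuple[str, ...]) -> list[str]:
    pairs = [(a, b) for a in alphabet for b in alphabet]
    return {
        "type_counts": [f"{t}(N)" for t in alphabet],
        "type_proportions": [f"{t}(P)" for t in alphabet],
        "pair_counts": [f"{a}_{b}(N)" for a, b in pairs],
        "pair_proportions": [f"{a}_{b}(P)" for a, b in pairs],
    }[block]


def select_representative(features: pd.DataFrame,
                          alphabet: tuple[str, ...] = ALPHABET,
                          blocks: tuple[str, ...] = FEATURE_BLOCKS) -> object:
    """The pup closest to the group median profile.

    Per feature block the columns are z-scored by the group's mean/SD and
    the Euclidean distance to the block's median vector computed; the
    representative minimizes the summed block distances (Markov
    probabilities are excluded).  Ties break to the lowest pup_id.
    """
    if len(features) == 0:
        raise ValueError("empty group")
    feats = features.set_index("pup_id") if "pup_id" in features.columns else features
    total = pd.Series(0.0, index=feats.index)
    for block in blocks:
        cols = [c for c in _block_columns(block, alphabet) if c in feats.columns]
        X = feats[cols].to_numpy(float)
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        med = np.median(Z, axis=0)
        total += np.sqrt(((Z - med) ** 2).sum(axis=1))
    best = total[total == total.min()].index
    return min(best)


# ---------------------------------------------------------------------------
# Acoustic-cluster trajectories

def cluster_trajectories(cluster_labels: np.ndarray, sequence_ids: np.ndarray,
                         n_clusters: int | None = None) -> np.ndarray:
    """Within-sequence adjacent cluster-transition counts (k x k).

    The cluster-level analogue of the call-type transition matrix: how
    call sequences move through the acoustic-feature clusters.
    """
    labels = np.asarray(cluster_labels)
    if np.any(pd.isna(labels)) or np.any(labels < 0):
        bad = np.where(pd.isna(labels) | (labels < 0))[0]
        raise ValueError(f"unlabeled calls at indices {bad[:10].tolist()}")
    k = n_clusters if n_clusters is not None else int(labels.max()) + 1
    M = np.zeros((k, k), dtype=int)
    sequence_ids = np.asarray(sequence_ids)
    same = sequence_ids[1:] == sequence_ids[:-1]
    for a, b in zip(labels[:-1][same], labels[1:][same]):
        M[int(a), int(b)] += 1
    return M
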