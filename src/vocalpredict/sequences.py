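"""Call-sequence segmentation and entropy profiles.

A call sequence (bout) is defined operationally: pool the inter-call
intervals of a genotype x age group, estimate their density, and find
where it first drops below the interval density a homogeneous Poisson
process with the same overall call rate would produce (an exponential
with rate lambda = total calls / total recording time).  Intervals shorter
than that crossing point join calls into one sequence; longer intervals
split sequences.

Entropy profile per pup: H0 = log2(number of distinct call types the pup
emitted); H1 = Shannon entropy of its call-type distribution over all
calls; Hk (k = 2, 3, 4) = per-symbol Shannon entropy of the empirical
k-gram distribution, with k-grams taken by a step-1 sliding window within
sequences only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gaussian_kde

from .config import PipelineConfig


class NoCrossingError(RuntimeError):
    """The observed and theoretical interval densities never cross.

    Typically means the observed intervals are indistinguishable from the
    Poisson expectation; a bandwidth override may help if the KDE is
    oversmoothed.
    """


@dataclass(frozen=True)
class IntervalModel:
    """Fitted interval model for one genotype x age group."""

    group: tuple
    lam_per_ms: float          # theoretical Poisson rate, calls per ms
    crossing_ms: float         # observed/theoretical density crossing
    n_intervals: int


def pooled_intervals_ms(df: pd.DataFrame) -> np.ndarray:
    """Onset-to-onset inter-call intervals (ms) pooled over sessions."""
    out = []
    for _, grp in df.groupby(["pup_id", "age_day"], sort=False):
        onsets = np.sort(grp["onset_s"].to_numpy(float))
        if len(onsets) >= 2:
            out.append(np.diff(onsets) * 1000.0)
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def crossing_point(intervals_ms: np.ndarray, lam_per_ms: float,
                   bw_method: str | float = "silverman",
                   grid_step_ms: float = 1.0,
                   t_max_ms: float | None = None) -> float:
    """First downward crossing of KDE(observed) over lambda*exp(-lambda*t).

    The observed interval density is a Gaussian KDE (Silverman bandwidth by
    default).  The crossing is bracketed by a sign scan on a ``grid_step_ms``
    grid starting at one step, then refined by bisection to 0.01 ms.
    Raises :class:`NoCrossingError` if no positive-to-negative sign change
    occurs on (0, t_max].
    """
    intervals_ms = np.asarray(intervals_ms, float)
    if intervals_ms.size < 2:
        raise ValueError("need at least 2 intervals")
    if lam_per_ms <= 0:
        raise ValueError("lam_per_ms must be positive")
    if t_max_ms is None:
        t_max_ms = float(intervals_ms.max())
    kde = gaussian_kde(intervals_ms, bw_method=bw_method)

    def g(t: float) -> float:
        return float(kde(t)[0] - lam_per_ms * np.exp(-lam_per_ms * t))

    t = grid_step_ms
    prev_t, prev_v = None, None
    while t <= t_max_ms:
        v = g(t)
        if prev_v is not None and prev_v > 0 and v < 0:
            return float(brentq(g, prev_t, t, xtol=0.01))
        if v != 0:
            prev_t, prev_v = t, v
        t += grid_step_ms
    raise NoCrossingError(
        "observed and theoretical interval densities do not cross; "
        "consider overriding the KDE bandwidth")


def fit_interval_model(df: pd.DataFrame, group: tuple,
                       config: PipelineConfig | None = None) -> IntervalModel:
    """Fit the interval model for one genotype x age group.

    ``df`` must contain only that group's calls.  The theoretical rate is
    lambda = total calls / total recording time, with the recording time
    per session taken from the configuration.
    """
    cfg = config or PipelineConfig()
    n_calls = len(df)
    if n_calls < 2:
        raise ValueError(f"group {group} has fewer than 2 calls")
    n_sessions = df.groupby(["pup_id", "age_day"]).ngroups
    lam = n_calls / (n_sessions * cfg.session_duration_s * 1000.0)
    intervals = pooled_intervals_ms(df)
    crossing = crossing_point(
        intervals, lam,
        bw_method=cfg.kde_bandwidth if cfg.kde_bandwidth is not None else "silverman",
        grid_step_ms=cfg.grid_step_ms,
        t_max_ms=cfg.session_duration_s * 1000.0)
    return IntervalModel(group=group, lam_per_ms=lam,
                         crossing_ms=crossing, n_intervals=len(intervals))


def fit_interval_models(df: pd.DataFrame,
                        config: PipelineConfig | None = None,
                        ) -> dict[tuple, IntervalModel]:
    """One interval model per genotype x age, fit on pooled intervals."""
    return {
        (geno, age): fit_interval_model(grp, (geno, age), config)
        for (geno, age), grp in df.groupby(["genotype", "age_day"], sort=True)
    }


def segment_sequences(onsets_s: np.ndarray, crossing_ms: float) -> np.ndarray:
    """Sequence id (0-based, consecutive) for each call of one session.

    A new sequence starts whenever the gap to the previous call is at
    least ``crossing_ms``.  Singleton sequences are allowed; the partition
    preserves call order and conserves every call.
    """
    onsets_s = np.asarray(onsets_s, float)
    if onsets_s.size == 0:
        return np.empty(0, dtype=int)
    gaps_ms = np.diff(onsets_s) * 1000.0
    return np.concatenate([[0], np.cumsum(gaps_ms >= crossing_ms)]).astype(int)


def segment_table(df: pd.DataFrame, models: dict[tuple, IntervalModel],
                  ) -> pd.DataFrame:
    """Add a ``sequence_id`` column, applying each group's crossing threshold."""
    out = df.copy()
    out["sequence_id"] = -1
    for (pup, geno, age), grp in out.groupby(["pup_id", "genotype", "age_day"],
                                             sort=False):
        model = models[(geno, age)]
        out.loc[grp.index, "sequence_id"] = segment_sequences(
            grp["onset_s"].to_numpy(), model.crossing_ms)
    return out


def sequence_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Per pup x age: number of sequences, mean calls/sequence, mean duration.

    Sequence duration = last call offset - first call onset (ms); the
    offset uses ``onset_s + duration_ms``.
    """
    if "sequence_id" not in df.columns:
        raise ValueError("call table has no sequence_id column; segment first")
    rows = []
    for (pup, geno, age), grp in df.groupby(["pup_id", "genotype", "age_day"],
                                            sort=True):
        lengths, durations = [], []
        for _, seq in grp.groupby("sequence_id", sort=True):
            lengths.append(len(seq))
            start = seq["onset_s"].iloc[0] * 1000.0
            end = seq["onset_s"].iloc[-1] * 1000.0 + seq["duration_ms"].iloc[-1]
            durations.append(end - start)
        rows.append({
            "pup_id": pup, "genotype": geno, "age_day": age,
            "n_sequences": len(lengths),
            "mean_calls_per_sequence": float(np.mean(lengths)),
            "mean_sequence_duration_ms": float(np.mean(durations)),
        })
    return pd.DataFrame(rows)


def _shannon(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_profile(types: np.ndarray, sequence_ids: np.ndarray,
                    mode: str = "per_symbol") -> dict[str, float]:
    """H0..H4 (bits) for one pup session.

    ``mode='per_symbol'`` divides the k-gram entropy by k (block entropy
    rate); ``mode='joint'`` reports it unscaled.  Hk is NaN when no k-gram
    exists (every sequence shorter than k).
    """
    types = np.asarray(types)
    sequence_ids = np.asarray(sequence_ids)
    if types.size == 0:
        raise ValueError("entropy_profile needs at least one call")
    out: dict[str, float] = {}
    distinct = np.unique(types)
    out["H0"] = float(np.log2(len(distinct)))
    _, counts = np.unique(types, return_counts=True)
    out["H1"] = _shannon(counts)
    for k in (2, 3, 4):
        grams: list[tuple] = []
        for sid in np.unique(sequence_ids):
            seq = types[sequence_ids == sid]
            grams.extend(tuple(seq[i:i + k]) for i in range(len(seq) - k + 1))
        if not grams:
            out[f"H{k}"] = np.nan
            continue
        _, counts = np.unique(np.array(["|".join(g) for g in grams]),
                              return_counts=True)
        h = _shannon(counts)
        out[f"H{k}"] = h / k if mode == "per_symbol" else h
    return out


def entropy_table(df: pd.DataFrame,
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Entropy profile per pup x age over a segmented, labeled call table."""
    cfg = config or PipelineConfig()
    rows = []
    for (pup, geno, age), grp in df.groupby(["pup_id", "genotype", "age_day"],
                                            sort=True):
        prof = entropy_profile(grp["call_type"].to_numpy(),
                               grp["sequence_id"].to_numpy(),
                               mode=cfg.entropy_mode)
        rows.append({"pup_id": pup, "genotype": geno, "age_day": age, **prof})
    return pd.DataFrame(rows)
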