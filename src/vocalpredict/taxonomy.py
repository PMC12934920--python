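"""Call-type classification from frequency contours.

Each detected call carries a frequency contour — ordered (time, frequency)
points of its principal component — plus a harmonic flag set upstream when
a simultaneous secondary component was detected.  A fixed decision tree
maps every contour to exactly one of the 13 call types; Amb (ambiguous) is
the only fall-through.

Decision order (thresholds in :class:`~vocalpredict.config.ClassifierThresholds`):

1. harmonic_flag                      -> Har
2. duration < short_ms                -> Sh
3. pitch jumps (|df| >= jump_hz within <= jump_ms):
   one up -> Su; one down -> Sd; exactly two -> Ts; three or more -> Ms
4. no jumps, excursion < flat_hz      -> F
5. monotone rise / fall               -> U / D
6. unique interior maximum (minimum) with excursion >= chevron_hz -> Ch (RCh)
7. two or more direction changes      -> Cx
8. otherwise                          -> Amb
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ClassifierThresholds, PipelineConfig, ALPHABET


class ContourError(ValueError):
    """Raised for contours that cannot be classified (fewer than 2 points)."""


@dataclass(frozen=True)
class Contour:
    """Ordered (time_ms, frequency_hz) points of a call's principal component."""

    times_ms: np.ndarray
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        f = np.asarray(self.freqs_hz, dtype=float)
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "freqs_hz", f)
        if t.size < 2 or f.size != t.size:
            raise ContourError("contour needs >= 2 (time, frequency) points")
        if (np.diff(t) <= 0).any():
            raise ContourError("contour times must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0])

    def serialize(self) -> str:
        return ";".join(f"{t:g}:{f:g}"
                        for t, f in zip(self.times_ms, self.freqs_hz))

    @classmethod
    def deserialize(cls, s: str) -> "Contour":
        pairs = [p.split(":") for p in s.split(";")]
        return cls(np.array([float(t) for t, _ in pairs]),
                   np.array([float(f) for _, f in pairs]))


def classify_call(contour: Contour, harmonic_flag: bool = False,
                  thresholds: ClassifierThresholds | None = None) -> str:
    """Classify one contour into the 13-type alphabet.

    Total and deterministic: every valid contour maps to exactly one label.
    """
    th = thresholds or ClassifierThresholds()
    if harmonic_flag:
        return "Har"
    if contour.duration_ms < th.short_ms:
        return "Sh"

    dt = np.diff(contour.times_ms)
    df = np.diff(contour.freqs_hz)
    jumps = df[(np.abs(df) >= th.jump_hz) & (dt <= th.jump_ms)]
    if len(jumps) == 1:
        return "Su" if jumps[0] > 0 else "Sd"
    if len(jumps) == 2:
        return "Ts"
    if len(jumps) >= 3:
        return "Ms"

    f = contour.freqs_hz
    excursion = float(f.max() - f.min())
    if excursion < th.flat_hz:
        return "F"
    signs = np.sign(df)
    nz = signs[signs != 0]
    if (nz > 0).all():
        return "U"
    if (nz < 0).all():
        return "D"
    n_changes = int(np.sum(nz[1:] != nz[:-1]))
    interior = f[1:-1]
    if n_changes == 1:
        if nz[0] > 0:  # rise then fall: interior maximum
            if (np.sum(f == f.max()) == 1 and interior.max() == f.max()
                    and excursion >= th.chevron_hz):
                return "Ch"
        else:          # fall then rise: interior minimum
            if (np.sum(f == f.min()) == 1 and interior.min() == f.min()
                    and excursion >= th.chevron_hz):
                return "RCh"
    if n_changes >= 2:
        return "Cx"
    return "Amb"


def canonical_contours(th: ClassifierThresholds | None = None,
                       ) -> dict[str, tuple[Contour, bool]]:
    """One fixture contour per call type, built against the decision tree.

    Returns ``{label: (contour, harmonic_flag)}`` covering all 13 labels.
    Used by the test suite and by the synthetic generator as contour
    templates.
    """
    th = th or ClassifierThresholds()
    J = th.jump_hz * 1.5           # a clear pitch jump
    E = th.chevron_hz * 1.5        # a clear excursion
    base = 60_000.0

    def c(times, freqs):
        return Contour(np.asarray(times, float), np.asarray(freqs, float))

    out: dict[str, tuple[Contour, bool]] = {
        "Har": (c([0, 20, 40], [base, base + 2000, base]), True),
        "Sh": (c([0, th.short_ms * 0.5], [base, base + 1000]), False),
        "Su": (c([0, 15, 16, 40], [base, base, base + J, base + J]), False),
        "Sd": (c([0, 15, 16, 40], [base + J, base + J, base, base]), False),
        "Ts": (c([0, 12, 13, 26, 27, 40],
                 [base, base, base + J, base + J, base + 2 * J, base + 2 * J]),
               False),
        "Ms": (c([0, 9, 10, 19, 20, 29, 30, 40],
                 [base, base, base + J, base + J, base, base, base + J, base + J]),
               False),
        "F": (c([0, 20, 40], [base, base + th.flat_hz * 0.3, base]), False),
        "U": (c([0, 20, 40], [base, base + E / 2, base + E]), False),
        "D": (c([0, 20, 40], [base + E, base + E / 2, base]), False),
        "Ch": (c([0, 20, 40], [base, base + E, base]), False),
        "RCh": (c([0, 20, 40], [base + E, base, base + E]), False),
        "Cx": (c([0, 10, 20, 30, 40],
                 [base, base + E, base + E * 0.4, base + E * 0.9, base + E * 0.2]),
               False),
        # plateau-topped arch: one direction change but no unique interior
        # extremum, so it falls through every shape rule
        "Amb": (c([0, 13, 27, 40], [base, base + E, base + E, base]), False),
    }
    return out


def classify_table(df: pd.DataFrame,
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Add/overwrite the ``call_type`` column by classifying each contour.

    Rows without a contour but with an existing ``call_type`` keep their
    label; rows with neither raise.
    """
    cfg = config or PipelineConfig()
    th = cfg.thresholds
    out = df.copy()
    labels = []
    has_contour = "contour" in out.columns
    for idx, row in out.iterrows():
        s = row["contour"] if has_contour else None
        if isinstance(s, str) and s:
            labels.append(classify_call(Contour.deserialize(s),
                                        bool(row["harmonic_flag"]), th))
        elif "call_type" in out.columns and isinstance(row.get("call_type"), str):
            labels.append(row["call_type"])
        else:
            raise ContourError(f"row {idx} has neither a contour nor a call_type")
    out["call_type"] = labels
    return out


def profile_calls(df: pd.DataFrame,
                  alphabet: tuple[str, ...] = ALPHABET,
                  roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per pup x age call-type counts and proportions.

    Returns one row per (pup_id, genotype, age_day) with ``n_calls``,
    ``<type>_n`` count columns and ``<type>_p`` proportion columns.
    ``roster`` (columns pup_id, genotype, age_day) lists the recorded
    sessions; sessions present there but absent from the call table are
    silent pups, reported with all-zero counts, NaN proportions and
    ``excluded=True`` (omitted from proportion summaries, the standard
    treatment of a pup that emitted no call).
    """
    if "call_type" not in df.columns:
        raise ValueError("call table has no call_type column; classify first")
    rows = []
    seen = set()
    for (pup, geno, age), grp in df.groupby(["pup_id", "genotype", "age_day"],
                                            sort=True):
        seen.add((pup, age))
        counts = grp["call_type"].value_counts()
        n = int(len(grp))
        row = {"pup_id": pup, "genotype": geno, "age_day": age,
               "n_calls": n, "excluded": n == 0}
        for t in alphabet:
            c = int(counts.get(t, 0))
            row[f"{t}_n"] = c
            row[f"{t}_p"] = c / n if n > 0 else np.nan
        rows.append(row)
    if roster is not None:
        for _, r in roster.iterrows():
            if (r["pup_id"], r["age_day"]) not in seen:
                row = {"pup_id": r["pup_id"], "genotype": r["genotype"],
                       "age_day": r["age_day"], "n_calls": 0, "excluded": True}
                row.update({f"{t}_n": 0 for t in alphabet})
                row.update({f"{t}_p": np.nan for t in alphabet})
                rows.append(row)
    return pd.DataFrame(rows)


def group_summary(profile: pd.DataFrame,
                  alphabet: tuple[str, ...] = ALPHABET) -> pd.DataFrame:
    """Mean and SEM of per-type counts and proportions per genotype x age."""
    use = profile[~profile["excluded"]]
    recs = []
    for (geno, age), grp in use.groupby(["genotype", "age_day"]):
        for t in alphabet:
            for kind in ("n", "p"):
                vals = grp[f"{t}_{kind}"].to_numpy(float)
                recs.append({
                    "genotype": geno, "age_day": age, "call_type": t,
                    "measure": "count" if kind == "n" else "proportion",
                    "mean": float(np.mean(vals)),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else np.nan,
                })
    return pd.DataFrame(recs)


def genotype_count_tests(profile: pd.DataFrame, age: int,
                         alphabet: tuple[str, ...] = ALPHABET,
                         fdr: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney U per call type between genotypes at one age, BH-adjusted.

    Normality/homoscedasticity routinely fail for call counts, hence the
    rank test.  Uses the normal approximation with tie correction (the
    group sizes here are well beyond exact-test range).
    """
    from scipy.stats import mannwhitneyu
    from statsmodels.stats.multitest import multipletests

    sub = profile[(profile["age_day"] == age) & (~profile["excluded"])]
    genos = sorted(sub["genotype"].unique())
    if len(genos) != 2:
        raise ValueError(f"need exactly 2 genotypes at age {age}, got {genos}")
    g1, g2 = genos
    recs = []
    for t in alphabet:
        a = sub.loc[sub["genotype"] == g1, f"{t}_n"].to_numpy(float)
        b = sub.loc[sub["genotype"] == g2, f"{t}_n"].to_numpy(float)
        method = "exact" if min(len(a), len(b)) <= 8 and not (
            len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        recs.append({"call_type": t, "U": float(res.statistic),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(recs)
    rej, adj, _, _ = multipletests(out["p"], alpha=fdr, method="fdr_bh")
    out["p_adj"] = adj
    out["significant"] = rej
    return out
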