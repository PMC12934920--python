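"""Predictor selection: Lasso over a penalty path with information-criterion
model choice, subsample stability counts, and per-feature correlations.

For each genotype x session the P12 call metrics (type counts/proportions,
two-call connection counts/proportions, Markov probabilities) and gene RQs
are pooled into one feature matrix against the affiliative social-
interaction score.  Features are z-scored jointly; the Lasso is solved by
coordinate descent on a 100-point log-spaced penalty path from
lambda_max = max|X'y|/n down to 1e-3 * lambda_max.

Model choice along the path uses the Gaussian information criterion

    n * ln(RSS / n) + 2 * df            (criterion="aic")

with df = number of nonzero coefficients.  At the sample sizes this
analysis targets (n ~ 25) the plain criterion is degenerate whenever more
features than samples are available — the bottom of the path interpolates
the response, RSS tends to 0 and the saturated model always wins — so the
default adds the small-sample (second-order) correction

    + 2 * df * (df + 1) / (n - df - 1)  (criterion="aicc")

which diverges as df approaches n and restores sparse selection.  Ties
break toward larger lambda (the sparser model).

Validation: the selection is repeated on five subsamples (dropping 5-6
mice each time); features selected in >= 3 of 5 repeats are flagged
stable.  Per-feature Pearson correlations with the response provide a
model-free cross-check of sign and rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path


@dataclass
class SelectionResult:
    feature_names: list[str]
    alphas: np.ndarray            # descending penalty path
    coefs: np.ndarray             # p x n_alphas, on the standardized scale
    rss: np.ndarray
    df: np.ndarray                # nonzero coefficients per path point
    r2: np.ndarray                # fraction deviance explained
    criterion: np.ndarray         # AIC(c) values along the path
    chosen_index: int
    selected: pd.Series = field(init=False)   # nonzero coefs at the chosen point
    dropped_constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        coef = self.coefs[:, self.chosen_index]
        nz = np.abs(coef) > 1e-10
        self.selected = pd.Series(coef[nz],
                                  index=np.array(self.feature_names)[nz])

    @property
    def chosen_alpha(self) -> float:
        return float(self.alphas[self.chosen_index])


def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Z-score columns; drop constants.  Returns (Z, kept, dropped)."""
    arr = X.to_numpy(float)
    sd = arr.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    arr = arr[:, keep]
    Z = (arr - arr.mean(axis=0)) / sd[keep]
    return Z, [c for c, k in zip(X.columns, keep) if k], dropped


def lasso_aic(X: pd.DataFrame, y: np.ndarray, criterion: str = "aicc",
              n_alphas: int = 100, eps: float = 1e-3) -> SelectionResult:
    """Fit the Lasso path and choose the penalty by information criterion.

    ``X`` is a mice x features frame (missing Markov probabilities should
    be imputed before calling); ``y`` the response.  Features are z-scored
    internally, so the selected set is invariant to affine rescaling of
    any feature.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need n >= 10 mice, got {n}")
    if np.var(y) == 0:
        raise ValueError("response has zero variance")
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"feature matrix has missing values in {bad[:5]}")
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")

    Z, kept, dropped = _standardize(X)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Z.T @ yc)) / n
    alphas = np.geomspace(lam_max, eps * lam_max, n_alphas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(Z, yc, alphas=alphas, max_iter=50_000)

    resid = yc[:, None] - Z @ coefs
    rss = (resid ** 2).sum(axis=0)
    tss = float((yc ** 2).sum())
    r2 = 1.0 - rss / tss
    df = (np.abs(coefs) > 1e-10).sum(axis=0)
    with np.errstate(divide="ignore"):
        crit = n * np.log(np.maximum(rss, 1e-300) / n) + 2 * df
    if criterion == "aicc":
        with np.errstate(divide="ignore"):
            corr = np.where(df <= n - 2,
                            2.0 * df * (df + 1) / np.maximum(n - df - 1, 1e-12),
                            np.inf)
        crit = crit + corr
    # alphas are descending, so the first argmin is the largest-penalty tie
    chosen = int(np.argmin(crit))
    return SelectionResult(feature_names=kept, alphas=alphas, coefs=coefs,
                           rss=rss, df=df, r2=r2, criterion=crit,
                           chosen_index=chosen, dropped_constant=dropped)


def stability_selection(X: pd.DataFrame, y: np.ndarray, seed: int,
                        n_repeats: int = 5,
                        n_drop: tuple[int, ...] = (5, 6, 5, 6, 5),
                        criterion: str = "aicc",
                        stable_threshold: int = 3,
                        ) -> tuple[pd.Series, list[pd.Series]]:
    """Re-run the Lasso selection on subsamples and count selections.

    Each repeat drops ``n_drop[r]`` mice uniformly at random (without
    replacement within a repeat, independently across repeats) and reruns
    :func:`lasso_aic`.  Returns ``(counts, per_repeat_selections)`` where
    ``counts`` holds, per feature, the number of repeats (out of
    ``n_repeats``) in which it was selected; counts >= ``stable_threshold``
    mark stable features.
    """
    y = np.asarray(y, float)
    n = len(y)
    if len(n_drop) < n_repeats:
        n_drop = tuple(n_drop[i % len(n_drop)] for i in range(n_repeats))
    if n - max(n_drop[:n_repeats]) < 10:
        raise ValueError("too few mice left after dropping")
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=X.columns, dtype=int)
    selections = []
    for r in range(n_repeats):
        keep = np.sort(rng.choice(n, size=n - n_drop[r], replace=False))
        res = lasso_aic(X.iloc[keep], y[keep], criterion=criterion)
        selections.append(res.selected)
        counts[res.selected.index] += 1
    return counts, selections


def correlation_validation(X: pd.DataFrame, y: np.ndarray,
                           features: list[str] | None = None) -> pd.DataFrame:
    """Pearson r of each (selected) feature with the response, ranked by |r|.

    Zero-variance features get NaN with a flag rather than an error.
    """
    from scipy.stats import pearsonr

    y = np.asarray(y, float)
    if len(y) < 3:
        raise ValueError("need n >= 3 for a correlation")
    cols = features if features is not None else list(X.columns)
    recs = []
    for c in cols:
        x = X[c].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            recs.append({"feature": c, "r": np.nan, "p": np.nan,
                         "flag": "zero-variance"})
        else:
            r, p = pearsonr(x, y)
            recs.append({"feature": c, "r": float(r), "p": float(p), "flag": ""})
    out = pd.DataFrame(recs)
    return out.sort_values("r", key=lambda s: s.abs(), ascending=False,
                           na_position="last").reset_index(drop=True)


def build_feature_matrix(call_features: pd.DataFrame, rq_wide: pd.DataFrame,
                         scores: pd.DataFrame, genotype: str, session: int,
                         age_day: int = 12,
                         impute_mp: float = 0.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the mice x features matrix and response for one model.

    ``call_features``: per pup x age feature vectors (P12 rows are used);
    ``rq_wide``: one row per mouse, one column per gene; ``scores``: per
    mouse x session social-interaction seconds (columns mouse_id, genotype,
    session, score).  Mouse IDs must match across tables — orphans raise,
    listing the missing IDs.  Missing Markov probabilities are imputed with
    ``impute_mp`` (absent transition = zero evidence); constant columns are
    retained here and dropped, with a record, inside :func:`lasso_aic`.
    """
    calls = call_features[(call_features["genotype"] == genotype)
                          & (call_features["age_day"] == age_day)].copy()
    calls = calls.drop(columns=["genotype", "age_day"]).set_index("pup_id")
    genes = rq_wide[rq_wide["genotype"] == genotype].drop(
        columns=["genotype"]).set_index("mouse_id")
    resp = scores[(scores["genotype"] == genotype)
                  & (scores["session"] == session)].set_index("mouse_id")["score"]

    ids = calls.index
    for name, other in (("expression", genes.index), ("scores", resp.index)):
        orphans = ids.difference(other)
        if len(orphans):
            raise ValueError(
                f"mice missing from {name} table: {sorted(orphans)[:10]}")
    genes = genes.loc[ids]
    resp = resp.loc[ids]
    X = pd.concat([calls, genes], axis=1)
    mp_cols = [c for c in X.columns if c.endswith("(MP)")]
    X[mp_cols] = X[mp_cols].fillna(impute_mp)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"unexpected missing values in features {bad[:5]}")
    return X, resp.to_numpy(float)
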