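"""Relative quantification (delta-delta-Ct) and group/variance statistics.

qRT-PCR quantification cycles are converted to relative expression with
the standard delta-delta-Ct model at amplification efficiency 2 (perfect
doubling per cycle):

    dCt  = Ct_target - Ct_housekeeping
    ddCt = dCt - mean(dCt | calibrator group)
    RQ   = 2 ** (-ddCt)

Calibration uses the arithmetic mean of dCt in the calibrator group
(equivalently the geometric mean of RQ), so the calibrator group's
geometric-mean RQ is exactly 1 for every gene.

Group comparisons per gene: Mann-Whitney U for location, Levene's test
(mean-centered, the common default in commercial stats packages) for
homogeneity of variance, with Benjamini-Hochberg control at the
configured FDR levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig


def compute_rq(df: pd.DataFrame, calibrator_genotype: str = "WT",
               ) -> pd.DataFrame:
    """Add ``dct`` and ``rq`` columns to a per-mouse Ct table.

    ``df`` needs columns mouse_id, genotype, gene, ct_target,
    ct_housekeeping (one row per mouse x gene, optionally per region —
    any extra grouping columns are carried through; calibration is per
    gene, or per gene x region when a ``region`` column is present).
    """
    required = {"mouse_id", "genotype", "gene", "ct_target", "ct_housekeeping"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    out = df.copy()
    out["dct"] = out["ct_target"] - out["ct_housekeeping"]
    group_cols = ["gene"] + (["region"] if "region" in out.columns else [])
    rqs = []
    for _, grp in out.groupby(group_cols, sort=False):
        cal = grp.loc[grp["genotype"] == calibrator_genotype, "dct"]
        if len(cal) == 0:
            raise ValueError(
                f"no {calibrator_genotype} mice to calibrate gene "
                f"{grp['gene'].iloc[0]!r}")
        ddct = grp["dct"] - cal.mean()
        rqs.append(np.power(2.0, -ddct))
    out["rq"] = pd.concat(rqs).reindex(out.index)
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted p_(i) = min over j >= i of (m * p_(j) / j), capped at 1;
    monotone non-decreasing in rank.
    """
    p = np.asarray(p_values, float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def genotype_tests(rq: pd.DataFrame, config: PipelineConfig | None = None,
                   genotypes: tuple[str, str] = ("WT", "Dup"),
                   levene_center: str = "mean") -> pd.DataFrame:
    """Per-gene location and variance tests with BH decisions.

    Mann-Whitney U (exact when the smaller group has <= 8 untied
    observations, normal approximation with tie correction otherwise) and
    Levene's W.  BH adjustment is applied across genes separately for the
    two test families; decisions are reported at every configured FDR
    level and are nested (significant at 5% implies significant at 10%
    and 25%).
    """
    cfg = config or PipelineConfig()
    g1, g2 = genotypes
    recs = []
    for gene, grp in rq.groupby("gene", sort=False):
        a = grp.loc[grp["genotype"] == g1, "rq"].to_numpy(float)
        b = grp.loc[grp["genotype"] == g2, "rq"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 mice per genotype")
        method = "exact" if (min(len(a), len(b)) <= 8
                             and len(np.unique(np.r_[a, b])) == len(a) + len(b)) \
            else "asymptotic"
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rec = {"gene": gene, "n_1": len(a), "n_2": len(b),
               "mwu_U": float(mwu.statistic), "mwu_p": float(mwu.pvalue)}
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            rec["levene_W"], rec["levene_p"] = np.nan, np.nan
            rec["levene_flag"] = "constant-data"
        else:
            lev = stats.levene(a, b, center=levene_center)
            rec["levene_W"], rec["levene_p"] = float(lev.statistic), float(lev.pvalue)
            rec["levene_flag"] = ""
        recs.append(rec)
    out = pd.DataFrame(recs)
    out["mwu_p_adj"] = bh_adjust(out["mwu_p"].to_numpy())
    lev_ok = out["levene_p"].notna()
    adj = np.full(len(out), np.nan)
    if lev_ok.any():
        adj[lev_ok.to_numpy()] = bh_adjust(out.loc[lev_ok, "levene_p"].to_numpy())
    out["levene_p_adj"] = adj
    for level in cfg.fdr_levels:
        pct = int(round(level * 100))
        out[f"mwu_sig_fdr{pct}"] = out["mwu_p_adj"] <= level
        out[f"levene_sig_fdr{pct}"] = out["levene_p_adj"] <= level
    return out


def rq_wide(rq: pd.DataFrame, region: str | None = None) -> pd.DataFrame:
    """Pivot a long RQ table to one row per mouse, one column per gene."""
    work = rq
    if region is not None and "region" in rq.columns:
        work = rq[rq["region"] == region]
    wide = work.pivot_table(index=["mouse_id", "genotype"], columns="gene",
                            values="rq")
    wide.columns.name = None
    return wide.reset_index()
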