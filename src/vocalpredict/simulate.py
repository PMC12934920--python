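"""Synthetic cohort generator.

Generates pup-call tables, qRT-PCR Ct tables and social-interaction score
tables with the statistical structure the analysis pipeline assumes, so
every downstream stage can be exercised and power-tested without the
original recordings.

Structure emulated per genotype (WT = wild type, Dup = paternal 15q11-13
duplication carrier):

* call counts per session ~ Poisson, with the Dup excess at P12;
* call types follow a first-order Markov chain (initial distribution pi,
  transition matrix T); the Dup chain has more off-diagonal mass ("more
  diverse call connections");
* inter-call (onset-to-onset) intervals from a two-component exponential
  mixture — a fast within-sequence rate and a slow between-sequence rate —
  so that an interval-density crossing against the Poisson expectation
  exists; the component drawn for each gap is recorded as the ground-truth
  bout structure;
* per-call acoustic features from one of four latent clusters shared
  across genotypes (genotype shifts only type frequencies, not cluster
  geometry);
* frequency contours built from the canonical per-type templates with
  tie-preserving jitter, so the contour classifier recovers the generating
  type;
* gene expression from a copy-number / imprinting model:
  Ct_target = Ct_housekeeping - log2(active_copies x amplification) + noise,
  with larger Ct noise for paternally expressed genes in Dup mice;
* social scores = genotype x session intercept + planted linear effects of
  named features + Gaussian noise, floored at 0, two sessions per mouse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import ALPHABET, ConfigError, ClassifierThresholds
from .taxonomy import Contour, canonical_contours

# ---------------------------------------------------------------------------
# Acoustic emission model: four latent clusters over seven features

#: Latent acoustic cluster of each call type (shared across genotypes).
TYPE_CLUSTER: dict[str, int] = {
    "Har": 0, "Su": 0,
    "Ts": 1, "Cx": 1, "Ms": 1, "Ch": 1,
    "D": 2, "Sh": 2, "F": 2, "U": 2,
    "Sd": 3, "RCh": 3, "Amb": 3,
}

#: Per-cluster emission parameters: minimum frequency, the two frequency
#: spans (min->mean, mean->max) and the maximum intensity, plus spreads.
#: Values are loosely modelled on pup USV ranges (50-100 kHz, -60..-20 dB);
#: the between-cluster separations are several within-cluster SDs so the
#: four clusters are genuinely distinct in feature space.
CLUSTER_PARAMS: list[dict[str, float]] = [
    {"fmin": 55_000, "span1": 20_000, "span2": 20_000, "imax": -22.0},
    {"fmin": 45_000, "span1": 15_000, "span2": 15_000, "imax": -32.0},
    {"fmin": 57_000, "span1": 3_000, "span2": 3_000, "imax": -42.0},
    {"fmin": 35_000, "span1": 8_000, "span2": 8_000, "imax": -52.0},
]
_FMIN_SD = 1_500.0
_SPAN_REL_SD = 0.10
_INT_SD = 1.5
_INT_STEP = 8.0       # mean drop max->mean and mean->min intensity (dB)


def sample_acoustic_features(types: np.ndarray,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Draw the 7 acoustic features for each call from its type's cluster."""
    n = len(types)
    clusters = np.array([TYPE_CLUSTER[t] for t in types])
    fmin = np.empty(n)
    span1 = np.empty(n)
    span2 = np.empty(n)
    imax = np.empty(n)
    for c in range(4):
        m = clusters == c
        p = CLUSTER_PARAMS[c]
        k = int(m.sum())
        fmin[m] = rng.normal(p["fmin"], _FMIN_SD, k)
        span1[m] = np.abs(rng.normal(p["span1"], p["span1"] * _SPAN_REL_SD, k))
        span2[m] = np.abs(rng.normal(p["span2"], p["span2"] * _SPAN_REL_SD, k))
        imax[m] = rng.normal(p["imax"], _INT_SD, k)
    imean = imax - np.abs(rng.normal(_INT_STEP, 1.0, n))
    imin = imean - np.abs(rng.normal(_INT_STEP, 1.0, n))
    fmean = fmin + span1
    fmax = fmean + span2
    return pd.DataFrame({
        "bandwidth_hz": fmax - fmin,
        "freq_max_hz": fmax, "freq_mean_hz": fmean, "freq_min_hz": fmin,
        "intensity_max_db": imax, "intensity_mean_db": imean,
        "intensity_min_db": imin,
        "acoustic_cluster_truth": clusters,
    })


# ---------------------------------------------------------------------------
# Genotype profiles

def _mixture_rows(pi: np.ndarray, self_weight: float) -> np.ndarray:
    return self_weight * np.eye(len(pi)) + (1 - self_weight) * np.tile(pi, (len(pi), 1))


#: Initial type distributions (alphabet order).  WT mass concentrates on
#: the simple shapes (D, Sh, F, U); Dup is flatter with more harmonic and
#: multi-wave types.
PI_WT = np.array([0.08, 0.05, 0.02, 0.02, 0.03, 0.02, 0.15,
                  0.04, 0.20, 0.15, 0.12, 0.04, 0.08])
PI_DUP = np.array([0.14, 0.10, 0.06, 0.07, 0.06, 0.06, 0.09,
                   0.07, 0.08, 0.08, 0.08, 0.05, 0.06])


@dataclass
class GenotypeProfile:
    label: str
    mean_call_count: dict[int, float]        # per age day
    initial: np.ndarray                      # pi over the 13 types
    transition: np.ndarray                   # 13x13 row-stochastic T
    lam_in_per_ms: float = 1 / 80.0          # within-sequence interval rate
    lam_out_per_ms: float = 1 / 2000.0       # between-sequence interval rate
    w_in: float = 0.9                        # mixture weight of the fast rate

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, float)
        self.transition = np.asarray(self.transition, float)
        if not np.isclose(self.initial.sum(), 1.0):
            raise ConfigError("initial distribution must sum to 1")
        rowsums = self.transition.sum(axis=1)
        if np.any(rowsums == 0):
            raise ConfigError("transition matrix has an all-zero row")
        if not np.allclose(rowsums, 1.0):
            raise ConfigError("transition matrix rows must sum to 1")
        if not (self.lam_in_per_ms > self.lam_out_per_ms > 0):
            raise ConfigError("need lam_in > lam_out > 0")
        if not (0.0 < self.w_in < 1.0):
            raise ConfigError("w_in must lie in (0, 1)")


def default_profiles() -> dict[str, GenotypeProfile]:
    """The cohort's generating profiles.

    Mean call counts are free parameters (no per-type count tables are
    published); they reproduce the qualitative Dup call excess at P12.
    """
    return {
        "WT": GenotypeProfile("WT", {8: 150.0, 12: 150.0}, PI_WT,
                              _mixture_rows(PI_WT, 0.30)),
        "Dup": GenotypeProfile("Dup", {8: 160.0, 12: 260.0}, PI_DUP,
                               _mixture_rows(PI_DUP, 0.15)),
    }


# ---------------------------------------------------------------------------
# Pup sessions

def _jitter_contour(contour: Contour, duration_ms: float,
                    rng: np.random.Generator, freq_sd: float = 250.0) -> Contour:
    """Rescale a template contour to ``duration_ms`` and jitter frequencies.

    Exact frequency ties in the template (e.g. the plateau of the
    ambiguous template) get identical jitter so the classified shape is
    preserved.
    """
    t = contour.times_ms * (duration_ms / contour.times_ms[-1])
    uniq, inv = np.unique(contour.freqs_hz, return_inverse=True)
    noise = rng.normal(0.0, freq_sd, size=len(uniq))
    return Contour(t, contour.freqs_hz + noise[inv])


def simulate_pup_session(profile: GenotypeProfile, age: int,
                         rng: np.random.Generator, pup_id: str = "P0",
                         thresholds: ClassifierThresholds | None = None,
                         with_contours: bool = True) -> pd.DataFrame:
    """One recording session: ordered calls with timing, contour and features.

    The returned table carries the generating truth alongside the
    observable columns: ``call_type`` (the Markov state),
    ``truth_sequence_id`` (which mixture component produced each gap) and
    ``acoustic_cluster_truth``.
    """
    n = int(rng.poisson(profile.mean_call_count[age]))
    templates = canonical_contours(thresholds)
    alphabet = list(ALPHABET)
    if n == 0:
        cols = ["pup_id", "genotype", "age_day", "onset_s", "duration_ms",
                "bandwidth_hz", "freq_max_hz", "freq_mean_hz", "freq_min_hz",
                "intensity_max_db", "intensity_mean_db", "intensity_min_db",
                "harmonic_flag", "contour", "call_type",
                "truth_sequence_id", "acoustic_cluster_truth"]
        return pd.DataFrame(columns=cols)

    # Markov chain of types (inverse-CDF sampling per step)
    cum_T = np.cumsum(profile.transition, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=int)
    states[0] = int(np.searchsorted(np.cumsum(profile.initial), u[0]))
    for i in range(1, n):
        states[i] = int(np.searchsorted(cum_T[states[i - 1]], u[i]))
    types = np.array([alphabet[s] for s in states])

    # intervals: two-component exponential mixture; the slow component
    # starts a new (true) sequence
    between = rng.random(n - 1) >= profile.w_in
    gaps_ms = np.where(between,
                       rng.exponential(1 / profile.lam_out_per_ms, n - 1),
                       rng.exponential(1 / profile.lam_in_per_ms, n - 1))
    onsets_s = (rng.uniform(0.0, 1.0) + np.concatenate([[0.0], np.cumsum(gaps_ms)]) / 1000.0)
    truth_seq = np.concatenate([[0], np.cumsum(between)]).astype(int)

    durations = np.where(types == "Sh", rng.uniform(3.0, 8.0, n),
                         rng.uniform(25.0, 80.0, n))
    feats = sample_acoustic_features(types, rng)

    rows = {
        "pup_id": pup_id, "genotype": profile.label, "age_day": age,
        "onset_s": onsets_s, "duration_ms": durations,
        "harmonic_flag": types == "Har",
        "call_type": types, "truth_sequence_id": truth_seq,
    }
    df = pd.DataFrame(rows)
    df = pd.concat([df, feats], axis=1)
    if with_contours:
        df["contour"] = [
            _jitter_contour(templates[t][0], d, rng).serialize()
            for t, d in zip(types, durations)
        ]
    order = ["pup_id", "genotype", "age_day", "onset_s", "duration_ms",
             "bandwidth_hz", "freq_max_hz", "freq_mean_hz", "freq_min_hz",
             "intensity_max_db", "intensity_mean_db", "intensity_min_db",
             "harmonic_flag"]
    order += ["contour"] if with_contours else []
    order += ["call_type", "truth_sequence_id", "acoustic_cluster_truth"]
    return df[order]


# ---------------------------------------------------------------------------
# Gene expression

@dataclass
class GeneSpec:
    name: str
    imprinting: str = "none"        # none | paternal_expressed | maternal_expressed
    inside_duplication: bool = True
    copies: dict[str, int] = field(default_factory=lambda: {"WT": 2, "Dup": 3})
    #: multiplies the effective dose in Dup mice; > 1 models
    #: over-proportional expression of the Mkrn3 kind
    amplification: float = 1.0
    noise_sd: dict[str, float] = field(default_factory=lambda: {"WT": 0.15, "Dup": 0.15})


def active_copies(spec: GeneSpec, genotype: str) -> float:
    """Transcriptionally active copies given imprinting status.

    The duplication is paternally inherited, so the extra copy follows the
    paternal allele's imprinting fate: a paternally expressed gene gains
    an active copy, a maternally expressed gene does not.
    """
    total = spec.copies[genotype]
    if total < 1:
        raise ConfigError(f"{spec.name}: copy count must be >= 1")
    if spec.imprinting == "none":
        return float(total)
    if spec.imprinting == "paternal_expressed":
        return float(total - 1)     # the single maternal copy is silenced
    if spec.imprinting == "maternal_expressed":
        return 1.0                  # only the maternal copy is active
    raise ConfigError(f"unknown imprinting status {spec.imprinting!r}")


def default_gene_panel() -> list[GeneSpec]:
    """The assayed panel: the duplicated-interval orthologs plus Cyfip1.

    Paternally expressed genes get larger Ct noise in Dup mice (the
    greater variability seen for that gene class); Mkrn3 carries a >1
    amplification factor for its over-proportional elevation.
    """
    pat = {"WT": 0.15, "Dup": 0.5}       # paternally expressed class
    var = {"WT": 0.15, "Dup": 0.4}       # non-imprinted genes with inflated
    # Dup variance (Herc2 / Gabrg3 / Gabrb3 in the assayed panel)
    panel = [
        GeneSpec("Herc2", noise_sd=dict(var)),
        GeneSpec("Gabrg3", noise_sd=dict(var)),
        GeneSpec("Gabra5"),
        GeneSpec("Gabrb3", noise_sd=dict(var)),
        GeneSpec("Atp10a"),
        GeneSpec("Snrpn", "paternal_expressed", noise_sd=dict(pat)),
        GeneSpec("Ndn", "paternal_expressed", noise_sd=dict(pat)),
        GeneSpec("Magel2", "paternal_expressed", noise_sd=dict(pat)),
        GeneSpec("Mkrn3", "paternal_expressed", amplification=1.3,
                 noise_sd=dict(pat)),
        GeneSpec("Ube3a", "maternal_expressed"),
        GeneSpec("Cyfip1", inside_duplication=False,
                 copies={"WT": 2, "Dup": 2}),
    ]
    return panel


@dataclass
class ExpressionModel:
    genes: list[GeneSpec] = field(default_factory=default_gene_panel)
    housekeeping_ct: float = 20.0
    region: str = "prefrontal_cortex"


def simulate_expression(model: ExpressionModel, mouse_ids: dict[str, list[str]],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Per mouse x gene Ct table.

    ``mouse_ids`` maps genotype -> list of mouse ids.
    Ct_target = Ct_housekeeping - log2(active_copies x amplification) + noise.
    """
    rows = []
    for geno, ids in mouse_ids.items():
        for spec in model.genes:
            dose = active_copies(spec, geno)
            if geno == "Dup":
                dose *= spec.amplification
            noise = rng.normal(0.0, spec.noise_sd[geno], size=len(ids))
            for mid, eps in zip(ids, noise):
                rows.append({
                    "mouse_id": mid, "genotype": geno, "gene": spec.name,
                    "region": model.region,
                    "ct_target": model.housekeeping_ct - np.log2(dose) + eps,
                    "ct_housekeeping": model.housekeeping_ct,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Social scores

@dataclass
class BehaviorModel:
    """Genotype x session intercepts (s) plus planted linear feature effects."""

    intercepts: dict[tuple[str, int], float] = field(default_factory=lambda: {
        ("WT", 1): 60.0, ("WT", 2): 50.0,
        ("Dup", 1): 55.0, ("Dup", 2): 75.0,
    })
    betas: dict[tuple[str, int], dict[str, float]] = field(default_factory=lambda: {
        # gene-expression route (the Magel2/Herc2 analogue): higher RQ,
        # lower social interaction; slopes are per RQ unit and sized so
        # both genes contribute ~2 noise-SD of score spread (Magel2's RQ
        # varies more, so its slope is smaller)
        ("Dup", 2): {"Magel2": -12.0, "Herc2": -20.0},
        # vocalization routes, sized to ~3 noise-SD given the typical
        # spread of each metric across pups (sparse pair metrics carry
        # little variance, so detectable slopes are necessarily large)
        ("Dup", 1): {"Har_D(N)": -8.0, "F_Sd(N)": 12.0},
        ("WT", 1): {"F_Ch(P)": -2000.0, "U_Amb(P)": 1800.0},
        ("WT", 2): {"Su_Su(P)": -1500.0},
    })
    noise_sd: float = 4.0
    sessions: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def simulate_social_scores(features: pd.DataFrame, model: BehaviorModel,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Scores per mouse x session from the planted linear model.

    ``features`` is one row per mouse (index mouse_id, a ``genotype``
    column, named feature columns).  Raises if a planted feature is
    missing.  Scores are truncated at 0.
    """
    rows = []
    for (geno, session), beta in _iter_cells(model):
        named = model.betas.get((geno, session), {})
        missing = [f for f in named if f not in features.columns]
        if missing:
            raise ConfigError(
                f"behavior model names features absent from the matrix: {missing}")
    for mid, row in features.iterrows():
        geno = row["genotype"]
        for session in model.sessions:
            mu = model.intercepts[(geno, session)]
            for fname, b in model.betas.get((geno, session), {}).items():
                mu += b * float(row[fname])
            score = max(0.0, mu + rng.normal(0.0, model.noise_sd))
            rows.append({"mouse_id": mid, "genotype": geno,
                         "session": session, "score": score})
    return pd.DataFrame(rows)


def _iter_cells(model: BehaviorModel):
    for key in model.intercepts:
        yield key, model.betas.get(key, {})


# ---------------------------------------------------------------------------
# Full cohort

@dataclass
class CohortConfig:
    n_wt: int = 29
    n_dup: int = 25
    ages: tuple[int, ...] = (8, 12)
    profiles: dict[str, GenotypeProfile] = field(default_factory=default_profiles)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    with_contours: bool = True


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    ) -> dict[str, pd.DataFrame | dict]:
    """Generate a linked cohort: calls at P8/P12, Ct table, social scores.

    Mouse IDs are shared across the three modalities.  Returns a dict with
    ``calls``, ``expression`` (Ct rows), ``scores`` and ``truth`` (the
    generating parameters, JSON-serializable).
    """
    from .expression import compute_rq, rq_wide
    from .transitions import pup_features

    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    mouse_ids = {
        "WT": [f"WT{i + 1:02d}" for i in range(cfg.n_wt)],
        "Dup": [f"Dup{i + 1:02d}" for i in range(cfg.n_dup)],
    }

    sessions = []
    for geno, ids in mouse_ids.items():
        profile = cfg.profiles[geno]
        for mid in ids:
            for age in cfg.ages:
                sessions.append(simulate_pup_session(
                    profile, age, rng, pup_id=mid,
                    with_contours=cfg.with_contours))
    calls = pd.concat(sessions, ignore_index=True)

    ct = simulate_expression(cfg.expression, mouse_ids, rng)

    # features the behavior model may reference: per-mouse P12 call metrics
    # (using the generator's own bout structure) plus gene RQs
    feat_rows = {}
    p12 = calls[calls["age_day"] == 12]
    for mid, grp in p12.groupby("pup_id", sort=False):
        feat_rows[mid] = pup_features(grp["call_type"].to_numpy(),
                                      grp["truth_sequence_id"].to_numpy())
    call_feats = pd.DataFrame(feat_rows).T.fillna(0.0)
    genes = rq_wide(compute_rq(ct)).set_index("mouse_id")
    features = genes.join(call_feats, how="left").fillna(0.0)
    scores = simulate_social_scores(features, cfg.behavior, rng)

    truth = {
        "seed": seed,
        "n_wt": cfg.n_wt, "n_dup": cfg.n_dup, "ages": list(cfg.ages),
        "profiles": {
            g: {"mean_call_count": p.mean_call_count,
                "initial": p.initial.tolist(),
                "transition": p.transition.tolist(),
                "lam_in_per_ms": p.lam_in_per_ms,
                "lam_out_per_ms": p.lam_out_per_ms, "w_in": p.w_in}
            for g, p in cfg.profiles.items()},
        "gene_panel": [asdict(s) for s in cfg.expression.genes],
        "behavior": {
            "intercepts": {f"{g}|{s}": v
                           for (g, s), v in cfg.behavior.intercepts.items()},
            "betas": {f"{g}|{s}": b for (g, s), b in cfg.behavior.betas.items()},
            "noise_sd": cfg.behavior.noise_sd},
        "type_cluster": TYPE_CLUSTER,
    }
    return {"calls": calls, "expression": ct, "scores": scores, "truth": truth}
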