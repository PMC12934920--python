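# Methods

This note records the models implemented in `vocalpredict`, the defaults
and their rationale, what the synthetic cohort does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Call classification

Each detected call carries a frequency contour (ordered time–frequency
points of its principal component) and a harmonic flag set by the
upstream detector when a simultaneous secondary component is present.
Classification is a fixed decision tree, total and deterministic:

1. harmonic flag → **Har**;
2. duration < `short_ms` → **Sh**;
3. count pitch jumps, i.e. contour steps with |Δf| ≥ `jump_hz` completed
   within ≤ `jump_ms`: one up → **Su**, one down → **Sd**, exactly two →
   **Ts**, three or more → **Ms**;
4. with no jumps: total excursion < `flat_hz` → **F**; monotone rise /
   fall (over the non-zero steps) → **U** / **D**; a unique interior
   maximum (minimum) with excursion ≥ `chevron_hz` → **Ch** (**RCh**);
   two or more direction changes → **Cx**; anything left → **Amb**.

Defaults (`jump_hz` 10 kHz, `jump_ms` 10 ms, `short_ms` 10 ms, `flat_hz`
and `chevron_hz` 6 kHz) are conventions from the USV-classification
literature, not published values; all are configuration fields. Two
deliberate readings of ambiguous cases: "two-steps" is implemented as
exactly two jumps regardless of direction, and a plateau-topped arch
(no unique interior extremum) falls through to **Amb** — with the default
`flat_hz == chevron_hz` that tie is the only route into **Amb**.

## Sequence (bout) segmentation

Inter-call intervals are measured onset-to-onset, consistent with the
Poisson event-count model that supplies the theoretical distribution: if
n calls occur in a session of duration T, a homogeneous Poisson process
with rate λ = n/T has interval density λe^{−λt}. Per genotype × age
group, intervals are pooled across pups (a single published threshold
per group implies pooling), their density is estimated by a Gaussian KDE
with Silverman's bandwidth (override exposed), and the segmentation
threshold is the first point where the KDE crosses the theoretical curve
from above — bracketed by a sign scan on a 1 ms grid and refined by
bisection to 0.01 ms. Gaps at or above the threshold split sequences;
singletons are allowed; the partition conserves calls and order, and
raising the threshold can only merge sequences.

Numerical behaviour: on 10,000 intervals drawn from Exp(1/100 ms) against
a theoretical Exp(1/400 ms), the estimator recovers the closed-form
crossing ln(4)/0.0075 ≈ 184.8 ms with a sampling SD of roughly 4–5 ms;
KDE smoothing adds a small rightward bias (≈2 ms at that geometry). When
the observed and theoretical densities never cross, a dedicated error
suggests a bandwidth override rather than returning a spurious root.

## Entropy profile

Per pup session: H₀ = log₂(number of distinct types the pup actually
emitted) — the realized alphabet, so H₀ varies across pups; H₁ is the
Shannon entropy of the call-type distribution over all calls; Hₖ
(k = 2, 3, 4) is the per-symbol block entropy H(k-gram)/k of the
empirical k-gram distribution, sliding window with step 1, k-grams taken
within sequences only. The per-symbol scaling makes the levels
comparable and reproduces the strict decline H₁ ≥ H₂ ≥ H₃ ≥ H₄ expected
of a stationary source (plain joint entropy is available via
`entropy_mode="joint"`). Hₖ is flagged undefined (NaN) when every
sequence is shorter than k.

## Transition models and tiers

Only within-sequence adjacent pairs count as connections. From the
13×13 count matrix: connection proportions Q = C/ΣC (sums to 1) and
Markov matrix P with rows normalized; rows with no outgoing connection
are flagged empty rather than propagating NaN. Salience tiers are
chance multiples: with K = 13 types, a cell earns the highest tier m ∈
{1.5, 2.0, 2.5} with P > m/K strictly (a cell exactly at chance gets no
tier). The thresholds print as 0.1154, 0.1538, 0.1923; note 2/13 =
0.153846 prints 0.1538, one ulp of print-rounding away from the 0.1539
sometimes quoted — the multiplier is configurable so either convention
can be reproduced.

The representative pup of a group minimizes the summed Euclidean
distances to the block-median vectors over four feature blocks (type
counts, type proportions, pair counts, pair proportions — Markov
probabilities excluded), each block z-scored by group statistics; ties
break to the lowest pup id.

## Acoustic embedding

Seven per-call features (bandwidth; max/mean/min frequency; max/mean/min
intensity) are z-scored column-wise — Hz and dB are incommensurate —
and embedded with UMAP (defaults n_neighbors 15, min_dist 0.1, 2-D;
fixed seed makes runs reproducible). Clusters are found by HDBSCAN on
the embedding with min_cluster_size defaulting to 2% of the calls; noise
labels are permitted, and `allow_single_cluster` must be enabled for a
lone cluster to be reportable (HDBSCAN discards the hierarchy root by
default). K-means with silhouette-selected k is available as an
alternative. Whether the original clusters were delineated
algorithmically is unknown; the density-based choice is a design
decision of this package.

## Expression statistics

Relative quantification uses the standard delta-delta-Ct model at
amplification efficiency 2 (perfect doubling; efficiencies are not
estimated): ΔCt = Ct_target − Ct_housekeeping, ΔΔCt subtracts the
arithmetic mean ΔCt of the WT calibrator group, RQ = 2^(−ΔΔCt) — so the
calibrator geometric-mean RQ is exactly 1 per gene. Group tests per
gene: Mann–Whitney U (exact when the smaller group has ≤8 untied values,
otherwise the normal approximation with tie correction) and Levene's
test mean-centered (the common commercial-package default;
median-centered Brown–Forsythe is an option). Benjamini–Hochberg
adjustment is applied per test family across genes, with decisions
reported at FDR 5/10/25% — nested by construction.

## Predictor selection

Per genotype × session, the feature matrix pools the 533 named P12 call
metrics — type counts `X(N)` and proportions `X(P)`, pair counts
`X_Y(N)`, pair proportions `X_Y(P)`, Markov probabilities `X_Y(MP)` —
with the gene RQs, jointly z-scored (so selection is invariant to affine
rescaling of any feature). Markov probabilities undefined for a pup
(empty source row) are imputed as 0: an absent transition is zero
evidence. Constant columns are dropped with a record.

The Lasso is solved by coordinate descent over 100 log-spaced penalties
from λ_max = max|Xᵀy|/n down to 10⁻³λ_max. Model choice along the path
uses the Gaussian Akaike criterion with df = number of nonzero
coefficients; the default adds the second-order small-sample correction
2df(df+1)/(n−df−1) (AICc). The correction matters structurally here:
with more features than mice the bottom of the path interpolates the
response, RSS → 0 and the uncorrected criterion diverges to −∞, so plain
AIC would always return the saturated model at these sample sizes; the
corrected criterion diverges to +∞ as df → n instead and restores sparse
selection. Plain AIC remains available (`criterion="aic"`). Ties break
toward the larger penalty (sparser model). Cross-validated penalty
choice is deliberately out of scope — at n ≈ 25 per cell the procedure
of record is information-criterion choice plus subsample stability.

Stability: five repeats, each dropping 5, 6, 5, 6, 5 mice uniformly at
random (independent across repeats), re-running the full selection and
counting per-feature appearances; ≥3 of 5 marks a feature stable.
Because the five subsamples share ~80% of the mice, their selections are
correlated — occasionally a noise feature repeats, so stability counts
are a validation heuristic, not a significance test. Per-gene Pearson
correlations with the response (ranked by |r|, sign reported) provide a
model-free cross-check.

## The synthetic cohort

Defaults are the study conditions: 29 WT + 25 Dup/+ mice, sessions at P8
and P12 of 300 s (the recording duration is not published; it is a
config value), 13-type alphabet, two social-interaction sessions.

- **Counts**: per-session call counts are Poisson with means WT 150/150
  and Dup 160/260 at P8/P12 — free parameters chosen only to reproduce
  the qualitative Dup call excess at P12; no per-type count tables are
  published to anchor them.
- **Types**: first-order Markov chains. Both genotypes' transition rows
  are a self-transition/repertoire mixture T = w·I + (1−w)·1πᵀ with
  WT (w = 0.30) concentrated on the simple shapes (D, Sh, F, U) and
  Dup (w = 0.15) flatter — more off-diagonal mass, i.e. more diverse
  call connections.
- **Timing**: onset-to-onset gaps from a two-component exponential
  mixture, within-sequence rate 1/80 ms⁻¹, between-sequence rate
  1/2000 ms⁻¹, weight 0.9 — the simplest mixture with a closed-form
  density crossing (≈270 ms at the WT call rate) and geometric bout
  lengths of mean 10.
- **Acoustics**: four latent clusters shared across genotypes (cluster
  geometry does not differ by genotype; only type frequencies do), with
  {Har, Su}, {Ts, Cx, Ms, Ch}, {D, Sh, F, U}, {Sd, RCh, Amb} mapped to
  clusters separated by several within-cluster SDs in the 7-feature
  space. Frequencies are built as min + positive spans and intensities
  as max − positive steps, so the min ≤ mean ≤ max invariants hold by
  construction.
- **Contours**: per-type canonical templates, time-rescaled to the
  call's duration and frequency-jittered (SD 250 Hz, far below every
  classifier threshold; exact template ties receive identical jitter so
  plateau shapes survive). The classifier recovers the generating type
  essentially always (>99.9% observed).
- **Expression**: Ct_target = Ct_housekeeping − log₂(active copies ×
  amplification) + N(0, σ) per gene, with active copies derived from
  total copies and imprinting status (the duplication is paternally
  inherited, so the extra copy follows the paternal allele's fate).
  Panel of 11 genes: five non-imprinted duplicated (Herc2, Gabrg3,
  Gabra5, Gabrb3, Atp10a; 3 vs 2 copies → RQ 1.5), four paternally
  expressed duplicated (Snrpn, Ndn, Magel2, Mkrn3; 2 vs 1 active → RQ
  2.0; Mkrn3 carries amplification 1.3 for its over-proportional
  elevation), maternally expressed Ube3a (RQ 1.0) and Cyfip1 outside
  the duplication (RQ 1.0). Ct noise is 0.15 cycles except for the
  gene classes reported as more variable in Dup/+ (the paternal class
  at 0.5, Herc2/Gabrg3/Gabrb3 at 0.4).
- **Behaviour**: score = genotype × session intercept + planted linear
  effects + N(0, 4 s), floored at 0. The Dup session-2 cell plants
  negative effects of Magel2 and Herc2 RQ sized so each contributes
  about twice the noise SD; the other cells plant call-metric effects
  (≈3 noise-SD — sparse pair metrics carry little variance, so
  detectable slopes are necessarily large in raw units). Intercepts
  (WT 60/50 s, Dup 55/75 s before the negative gene contributions)
  keep scores clear of the zero floor.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: raw audio and detection errors; any
dependence of acoustic features on the emitting pup (calls are i.i.d.
given type) or between a call's contour and its quantitative features;
session-level drift or litter effects; age-dependence of the transition
structure; and measurement-level Ct artefacts (plate effects,
efficiency < 2). One structural consequence of the multiplicative Ct
noise model: RQ spread scales with the RQ mean, so even genes with equal
Ct noise in both genotypes show larger Dup RQ variance at these sample
sizes — the variance findings on synthetic data are therefore broader
than the published gene list.

## Determinism and problem sizes

All randomness flows from explicit seeds (`numpy.random.default_rng`);
identical configuration and seed reproduce every table byte for byte.
Tests run the generator at reduced cohort sizes (8 + 8 mice) for the
shared fixtures and at the full 29 + 25 for the selection and acceptance
checks; convergence oracles use 10⁴–10⁵ draws, chosen so each check's
sampling error sits well inside its asserted tolerance.
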