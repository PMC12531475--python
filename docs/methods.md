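# Methods

## Scope and data model

The package analyses binary (positive/negative) ratings of N patients by
R observers, or by one observer on R occasions. All statistics depend on
the data only through the 2×2 pair tables and, for R > 2, the per-patient
counts (m_i1, R_i) of positive and total ratings. Missing ratings are
handled available-case: each patient contributes through their own R_i,
and patients with fewer than two ratings are flagged and excluded from
estimation (never silently dropped at read time). Point estimates are
computed in exact rational arithmetic from integer counts and converted to
float only at the presentation or inference boundary, so algebraic
identities (pJ = ppos/(2−ppos); po as the marginal-weighted mean of ppos
and pneg; two-rater reduction of every multi-rater formula) hold exactly
and are asserted exactly in the tests.

Degenerate inputs yield an explicit undefined state with a reason (e.g.
ppos when nobody rated anyone positive; kappa when chance agreement is 1),
never NaN or 0. Requesting the float value of an undefined coefficient
raises.

## Chance models and coefficient ordering

Three chance models are implemented for kappa: uniform (pe = 1/2; G
index / PABAK), rater-specific marginals (Cohen for pairs, Conger/Hubert
for R > 2; requires a complete matrix because each rater's marginal must
be estimable), and pooled marginals (Scott's pi, Fleiss for R > 2; allows
variable R_i with the pooled prevalence taken as Σm_i1/ΣR_i, the
ratings-weighted convention). Krippendorff's alpha is the pooled-marginal
model with Bessel-corrected expected disagreement, implemented in the
coincidence-matrix form for variable R_i; an independent coincidence-matrix
oracle in the tests confirms the pair-level closed form
qe = (NR/(NR−1))·2·p̄1·p̄2. Gwet's AC1 compares observed agreement with
pooled-marginal chance *disagreement*.

κ2 ≥ κ3 is a theorem (AM-GM on the marginals) and is tested
unconditionally. κ1 ≥ κ2 holds only when all marginals lie on the same
side of 1/2 (equivalently pe₂ ≥ 1/2); with marginals straddling 1/2 the
reverse ordering occurs and is itself diagnostic of clashing rating
styles. The property tests condition on the same-side regime.

For specific agreement with R > 2 two generalizations are provided:
averaging the pair indices (interpretable, but no analytic SE and the
Jaccard identity fails) and pooling numerators and denominators across
pairs (the default; keeps the identity and admits a delta-method SE). The
pooled ppos is Σ m_i1(m_i1−1)/(R_i−1) / Σ m_i1, which for equal R equals
Σ m_i1(m_i1−1) / ((R−1) Σ m_i1); this reading reproduces the worked
example (0.66 for the five observers). The mean-of-pairs route requires
every pair index to be defined and reports the offending pairs otherwise.

## Standard errors

Pair-level (multinomial delta method, closed forms):

* po: sqrt(po(1−po)/N);
* κ1 = 2po − 1: twice the po SE;
* Cohen's kappa: the Fleiss–Cohen–Everitt large-sample variance (the
  general form, not the κ=0 null form many packages report);
* intraclass kappa (pooled marginals): the Bloch–Kraemer variance
  (1−κ)/N · [(1−κ)(1−2κ) + κ(2−κ)/(2p̄q̄)];
* ppos/pneg: 4·p11·s·(p11+s)/(N·D⁴) with s = p12+p21, D = 2p11+s (and
  symmetrically for pneg). The linear term of the delta expansion
  vanishes identically, which the derivation in the test oracle exploits.

Multi-rater coefficients are smooth functions of per-patient means, so
their variance is estimated from per-patient influence values
(var = Σ(u_i−ū)²/(N(N−1))), the same linearization used in the irrCAC
family: the agreement statistic a_i for po; ratio linearization for pooled
ppos/pneg; and for each kappa the combined po and pe influence,
[(a_i−po) − (1−κ)(pe_i−pe)]/(1−pe), where pe_i linearizes the chance term
(Conger's pe equals the mean over ordered rater pairs of marginal
products, which supplies its per-patient derivative). Seeded patient
bootstraps agree with every analytic SE within 15% on the worked example
and on simulated matrices, and the five-observer Wald bounds land within
0.01–0.02 of the published table (these depend mildly on the joint rating
patterns, see "fixture" below). Mean-of-pairs specific agreement has no
per-patient linearization; requesting its analytic SE raises and points to
the bootstrap.

Interval constructions: Wald (clamped to the coefficient's range, with a
flag), a Yates-type continuity correction for the pair po (±1/(2N)),
patient-resampling percentile bootstrap (B = 2000 default, seed
mandatory, undefined replicates dropped and counted, >50% undefined
aborts), and Fisher-Z. Near the upper boundary (κ ≈ 0.9, N = 30) the
clamped Wald interval overcovers (≈0.99 empirical coverage at nominal
0.95) while Fisher-Z sits closer to nominal (≈0.92); at κ ≈ 0.8 Fisher-Z
is both closer and higher. The coverage test asserts closeness to nominal
rather than raw coverage for this reason. Simulated coverage of the Wald
interval for Cohen's kappa at N = 100, κ = 0.5 falls in [0.92, 0.97].

## The CTG fixture

The 20×5 worked-example matrix is not printed in full anywhere; it is
pinned down (up to row order and possibly not uniquely) by its sufficient
statistics: per-rater positive counts (6, 6, 9, 7, 12) and the ten
pairwise agreement proportions. Each pair's joint-positive count follows
exactly from n11 = (N·po − N + na + nb)/2 — parity or range violations
would prove the summaries inconsistent — and a committed matrix satisfying
all fifteen constraints was found by integer programming
(`search_rating_matrix`, scipy's HiGHS MILP backend, deterministic row
ordering). Every point estimate in the package depends on the data only
through these statistics, so the fixture reproduces all published
estimates exactly. Multi-rater standard errors additionally depend on the
per-patient pattern multiset and are therefore fixture-dependent; they are
asserted at ±0.02 and in fact agree with the published bounds within
±0.01.

## Sample-size planning

Both planning modes need Var(â) at N = 1 for the per-patient agreement
statistic a_i. The planning model is the dichotomous latent-class model:
a patient is truly positive with probability τ, raters classify
independently with common accuracy h, so h² + (1−h)² equals the target
pairwise agreement and τ matches the marginal positive rate. The two
inputs (prevalence, target agreement) identify the model exactly, and it
is the unique common-correlation construction in which disjoint rater
pairs are uncorrelated. Feasibility requires po ≥ 1 − 2π(1−π) (implied
pairwise kappa ≥ 0); infeasible requests report the attainable range.
For R = 2 the variance reduces to po(1−po).

CI-width mode returns the smallest integer N with
2·z_{1−α/2}·sqrt(Var₁/N) ≤ w; power mode the smallest N with
Φ((ρA−ρ0)/sqrt(Var₁(ρA)/N) − z_{1−α}) ≥ 1−β (one-sided, matching
H1: ρ > ρ0). Minimality is asserted cell by cell, monotonicity in R and
in the width/power holds, and simulating the planning model at the
returned N confirms the achieved width and power within Monte-Carlo error
(2000 replicates in the tests). Alternative mixing laws were examined
when freezing this default: beta-binomial and latent-Gaussian (probit)
mixing give materially larger higher-order moments and reproduce the
reference power table far less closely than the latent-class model, which
matches it within one to two patients across R = 3..8; no per-patient
variance model of any kind can reproduce the reference CI-width table for
R ≥ 4 (its implied variance exceeds the attainable bound
E[(pq)²] ≤ pq_max·E[pq] for every mixing law), so that table is not a
validation target for this mode beyond R = 3.

## Synthetic data

`simulate_common_correlation` draws each patient's positive probability
from a beta distribution with mean π and intraclass correlation ρ (the
two-parameter common-correlation construction compatible with the one-way
ANOVA reading of the intraclass kappa; ρ = 0 and ρ = 1 handled
analytically), then rates conditionally independently. The intraclass
kappa recovers ρ with bias < 0.02 at N = 1000, R = 5, and pairwise
agreement obeys qo = 2π(1−π)(1−ρ). `simulate_rater_shift` dichotomizes an
equicorrelated Gaussian at rater-specific cutpoints, producing marginal
heterogeneity (rating-style differences) that opens the κ2/κ3 gap and can
push κ2 above κ1. `simulate_intra_rater` makes replicates conditionally
iid within patient, so occasion labels are exchangeable and first-vs-random
occasion selection is equal in distribution. The generators emulate
exchangeable patients and (conditionally) independent raters; they do not
model patient-by-observer interaction, drift between occasions, or
informative missingness, so passing tests speak to the estimators under
those idealizations, not to such features of real data. All generators
require an explicit seed; outputs can be written with a JSON provenance
sidecar.

## Problem sizes in the test suite

The suite runs the worked example exactly; stochastic checks use
N = 100–2000 patients and 20–2000 replicates per assertion (bootstraps
B = 300–2000), sized so every Monte-Carlo tolerance is at least three
standard errors wide. The full suite completes in about a minute on one
core.
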