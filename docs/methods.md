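# Methods

This note documents the statistical procedures the package implements, the
defaults it ships, what the synthetic generator does and does not emulate,
and the numerical and design choices a maintainer should know about.

## Costing model

Costs are linear in utilisation, from the health and social care
perspective, in GBP at 2021/22 prices (no discounting over the 28-week
horizon).  Three recall periods partition the timeline: a baseline window
(default 12 weeks before randomisation — the recall length is a convention,
configurable in `Period`), weeks (0, 16], and weeks (16, 28].

* Community cost = Σ services contacts × per-contact unit cost.
* In-patient cost = psychiatric bed-days × per-diem.
* Therapy cost (intervention arms only) = attended sessions × therapist
  session cost + fixed technology charge.  The session cost is a
  senior-band (Band 8) rate multiplied by a 1.51 non-contact uplift;
  the shipped default (54.5 × 1.51 ≈ £82.3/session) is calibrated so that
  typical doses of ~5 and ~8 sessions cost ≈£420 and ≈£674 of therapist
  time.  The £50 fixed charge applies once per therapy recipient;
  a switch (`charge_fixed_without_sessions=False`) restricts it to
  participants with ≥1 session.
* Therapy cost is attributed to the w16 period (therapy is delivered during
  the treatment phase, which ends at the 16-week assessment); only the
  w16+w28 total enters the analysis, so the attribution is cosmetic.

The shipped unit-cost table contains representative NHS 2021/22 values for
the eight default services; it is a documented default, not a published
reference schedule, and any value can be overridden via `unit_costs.csv`.
Missing service-use is distinguished from zero use through per-period
attendance flags on the roster: an attended assessment with no rows is zero
use; an unattended one is missing and the period total is NaN.

## Utilities and QALYs

EQ-5D-5L profiles (3125 states) are valued with a pluggable `ValueSet`.
The packaged set is a *synthetic crosswalk*: each domain's five levels are
collapsed deterministically onto three (1→1, {2,3}→2, {4,5}→3) and scored
with the published UK three-level TTO tariff (constant decrement 0.081,
domain decrements, extreme-level decrement 0.269).  It anchors full health
at exactly 1.0 and bottoms out at −0.594, but it is not the published
regression-based 5L→3L mapping; substituting that mapping (or a direct 5L
tariff) is a one-line change via `ValueSet.read_csv`.  The country value
set is therefore a configuration concern, not hard-coded.

QALYs use the trapezoid rule over weeks 0/16/28 (linear change between
assessments), divided by 52 to give years; full health over 28 weeks is
28/52 ≈ 0.5385.  A participant missing any of the three utilities gets a
missing QALY and enters imputation.  No mortality is modelled.

## Missing data

Chained-equation imputation with predictive mean matching (PMM), donor
pool k = 5.  Each incomplete analysis variable (follow-up cost, QALY,
baseline cost, baseline utility) is regressed on all other analysis
variables plus arm and site indicators; regression parameters are drawn
from their approximate posterior (normal draw around the least-squares
estimate with a scaled inverse-chi-squared variance draw), and each missing
case receives the observed value of a donor drawn uniformly from the k
observed cases with nearest fitted means.  Exact distance ties are broken
by an infinitesimal seeded jitter.  Defaults: m = 10 imputations (the
number is an analysis choice, configurable), 10 cycles, seeded substreams
per imputation.  A dataset with no missing values passes through unchanged
(m identical copies), making the MI pipeline coincide exactly with a direct
fit — this is asserted in the tests.

## Estimation

Each completed dataset is analysed with a two-equation seemingly unrelated
regression:

* follow-up cost ~ arm + baseline cost + site,
* QALYs ~ arm + baseline utility + site,

estimated jointly by one-step feasible GLS with the OLS residual
cross-covariance.  The QALY equation retains site by default
(`include_site_in_qaly=False` removes it).  The TAU-referenced arm
coefficients are the incremental estimates; the joint covariance carries
the cross-equation correlation.  Numerically, each equation is scaled by
its residual s.d. and the GLS system is solved in least-squares (QR) form,
which keeps the Kruskal equivalence — identical regressor sets ⇒ FGLS
equals per-equation OLS — accurate to ~1e-10.  Singular designs (a site
emptied or collapsed into one arm by resampling, or constant baselines in
degenerate data) are repaired by dropping site indicators first, then
baseline covariates, with a warning; arm contrasts are never dropped.  A
singular residual covariance (exact-fit data) falls back to per-equation
OLS, which is then already exact.

Per-imputation estimates are pooled with Rubin's rules; interval estimates
use a t reference with Barnard–Rubin small-sample degrees of freedom
(complete-data df = n − p per equation; zero between-imputation variance
recovers the complete-data df).  Decisions: lower cost & more QALYs ⇒
dominant; higher cost & fewer QALYs ⇒ dominated; otherwise
ICER = ΔC/ΔQ in the NE or SW quadrant.  A delta exactly zero yields no
ICER and falls to the weak dominance class by cost sign.  The two therapy
arms are each compared with TAU only, never with each other.

The available-case analysis (per-equation OLS on each equation's own
complete cases, no imputation) is reported alongside as a sensitivity
method; its cross-equation covariance is not estimated.

## Probabilistic analysis

Bootstrap resampling is stratified by arm (preserving the 115/116/114
design; unstratified resampling is available by flag and redraws once if an
arm empties).  Each of B draws (default 1000) re-runs the imputation on the
resample with m_boot = 2 imputations — only point estimates are needed per
draw, so a small m_boot trades no bias for speed — fits the SUR, and
records the pooled (ΔC, ΔQ) per comparison plus regression-adjusted
per-arm means at the resample's covariate means.  Draws use independent
seeded substreams: a rerun with the same seed is bit-identical.

CEACs: pairwise mode (the default, matching two-option acceptability
figures) reports P(λ·ΔQ − ΔC > 0) + ½·P(= 0) per comparison; three-way
mode ranks all three arms' absolute net benefits λ·Q̄ − C̄ per draw and
splits exact ties equally.  Because adjusted arm means differ by exactly
the arm coefficients, the two-option ranking construction and the direct
INB count coincide identically — asserted in the tests.  Plane quadrants
assign boundary draws (a delta exactly zero) to the weakly-negative side;
with continuous bootstrap estimates this is measure-zero.

## Deterministic sensitivity scenarios

Scenarios replace the fixed technology charge (£25–£150) and scale the
therapist session cost (×0.5–×1.5).  Therapy cost is a deterministic
linear functional of each participant's observed session count, so a
scenario changes every intervention-arm participant's follow-up cost by a
known amount and cannot touch utilities.  The default engine therefore
runs the MI+SUR pipeline once under base-case costs and shifts each
comparison's incremental cost by the exact arm-mean therapy-cost change.
This makes the scenario table exactly self-consistent even with missing
data: ΔQ is identical across scenarios, ICER(fixed=75) − ICER(fixed=50) =
25/ΔQ, and a dominant comparison flips to a positive ICER precisely when
the added therapy cost exceeds the base-case saving.  A `refit` engine
re-runs the full pipeline per scenario with a shared seed for
cross-checking; on complete data it agrees with the offset engine for
fixed-cost scenarios exactly and for therapist scenarios up to the
(small) covariate-imbalance projection of the dose variable.

## Synthetic trial generator

The generator emulates the *structure* the analysis assumes, at the trial's
design conditions; it does not attempt to reproduce any real participant
data or published estimates.

* **Design**: arms 115/116/114 (TAU/brief/extended), four sites assigned
  uniformly, randomisation order shuffled.
* **Service use**: per period and service, a use probability and a
  zero-truncated Poisson contact count (shipped laws are representative of
  a community psychosis sample: GPs, psychiatrists and mental-health nurses
  used by ~45–55%, psychologists and early-intervention teams by ~25–33%),
  identical across arms, so community costs add variance but no arm effect.
* **Admissions**: rare Bernoulli events (per-arm probabilities ~0.06–0.08
  over follow-up) with gamma lengths of stay (shape 0.9; per-arm means
  76.7/70.0/27.9 days), clipped to the containing period, at a £341
  per-diem — a handful of admissions dominating cost variance is exactly
  the skewness the analysis must withstand.
* **Therapy dose**: beta-binomial counts on support 0..7 (brief) and 0..13
  (extended) — the assessment session plus the maximum dialogue count —
  with exact means 5.1/8.2 and s.d. near 2.4/4.4.  (On a bounded support
  the requested s.d. is only attainable with the extra assessment session
  included; the beta-binomial reproduces the completer-heavy shape.)
* **Utilities**: a participant-level latent level (mean 0.62, s.d. 0.20)
  plus occasion noise (s.d. 0.10) and small arm×time shifts at weeks 16/28
  (defaults +0.045/+0.033 brief, +0.050/+0.033 extended — chosen to imply
  28-week QALY gains near 0.016–0.017), projected to the *nearest
  attainable state* of the packaged value set with seeded tie-breaking.
  The projection is a modelling convenience, not a claim about real
  response patterns.
* **Missingness**: per-variable, per-arm MAR logistic models on
  standardized baseline utility (coefficient −1.2: sicker participants
  drop out more) and log baseline cost (+0.25), with intercepts solved so
  realised rates hit the per-arm targets (~10–27%, mirroring observed
  follow-up in trials of this design).  Baseline cost and the roster are
  never missing; a target of 1.0 is rejected because the MAR model
  conditions on those variables.
* **Ground truth**: `compute_truth` records the implied true (ΔC, ΔQ) per
  comparison — exact beta-binomial therapy-cost means plus common-random-
  numbers Monte Carlo (default 4×10⁵ participants/arm) for the admission
  and QALY components.  CRN makes a zero-effect configuration's truth
  exactly (0, 0).  `config_with_target_effects` inverts the generator
  approximately: the cost target uses the closed-form clipped-gamma stay
  expectation (accurate to Monte-Carlo error); the QALY target ignores
  state-grid discretisation and is attenuated a few percent — recovery
  tests therefore compare against the *recorded* truth, not the request.

What passing tests on this generator do **not** show: robustness to
non-MAR dropout, to utility distributions concentrated on salient states
(real EQ-5D responses cluster; the nearest-state projection spreads), to
arm-differential community service use, or to cost distributions heavier-
tailed than gamma admissions.

## Problem sizes and tolerances in the test suite

Validation checks run at sizes chosen to make their Monte-Carlo error
comfortably smaller than the asserted tolerance: Kruskal equivalence at
n = 345 (tolerance 1e-8); MCAR unbiasedness at n ≈ 1000 over 50
replications (2 MC standard errors); CI coverage at the trial's n = 345
over 100 replications with m = 10 (≥ 90/100 nominal-95% coverage for both
ΔC and ΔQ); bootstrap-vs-analytic interval agreement on homoskedastic data
at B = 600 (10% relative half-width — on skewed cost data robust and
model-based intervals genuinely differ, which is why the bootstrap is the
reported uncertainty); end-to-end determinism at B = 200.  The acceptance
script uses the full B = 1000.

## Known limitations

* The packaged value set is a level-collapse crosswalk, not the published
  regression mapping; absolute utility levels (and hence QALY levels) shift
  slightly under the real mapping, though the pipeline is agnostic.
* The cost equation is Gaussian-homoskedastic; with rare large admissions
  its analytic CIs are approximate, which is why the bootstrap CEAC is the
  primary uncertainty summary.
* Imputation treats follow-up cost and the QALY at the summary level
  rather than imputing per-period costs and per-week utilities.
* No societal-perspective costs, no discounting (≤28 weeks), no direct
  comparison between the two therapy arms, and no value-of-information
  analysis.
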