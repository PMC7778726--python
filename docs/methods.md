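# Methods

`cortipk` implements a population pharmacokinetic analysis of
dexamethasone (DEX) and betamethasone (BET) given as phosphate ester
prodrugs intramuscularly (IM) or orally (PO), including the one-to-one
betamethasone phosphate/acetate IM suspension (BET-PA). This note
documents the model, the estimation machinery, the synthetic-study
generator, and the numerical and design choices, in enough detail to
reproduce or audit any number the package prints.

## Structural model

Plasma kinetics of the free alcohol follow a linear two-compartment
disposition model with up to three parallel first-order absorption
depots (IM phosphate, oral, IM acetate):

    Vp dCp/dt = ka_IM A_IM + ka_PO A_PO + ka_IMa A_IMa
                - (CL + CL_D) Cp + CL_D CT
    VT dCT/dt = CL_D (Cp - CT)
    dA_x/dt   = -ka_x A_x

with initial depot amounts equal to the administered dose times the
absorbed fraction. Without an intravenous reference the absolute
bioavailability F_IM is unidentifiable, so clearances and volumes are
apparent (CL/F_IM, Vp/F_IM, CL_D/F_IM, VT/F_IM) and the oral and acetate
depots carry relative bioavailabilities Fr = F_PO/F_IM and
Fra = F_IMa/F_IM. Disposition parameters are shared across routes and
formulations within a drug.

Units throughout: mg doses, L volumes, L/h clearances, 1/h rates, hours,
and ng/mL concentrations; the mg-to-ug conversion happens inside the
concentration evaluator so that ug/L coincides with ng/mL and the
0.1 ng/mL quantification limit needs no unit juggling.

The primary evaluation path is the closed-form solution: each dose
contributes a tri-exponential response in exp(-alpha t), exp(-beta t),
exp(-ka t), and linearity makes any dose history a superposition of
per-dose responses. alpha and beta are the roots of
s^2 - (k10+k12+k21)s + k10 k21, with the smaller root computed from the
root product to avoid cancellation. Adaptive ODE integration of the same
system is kept in the test suite as an independent oracle; the two agree
to 1e-6 relative (floored at 1e-6 of the profile peak, which is where
double precision and any ODE integrator stop being meaningful) across
1000 random parameter draws over 0-400 h.

Removable singularities (an absorption rate numerically equal to a
disposition exponent) are evaluated by the analytic limit form in the
public `concentration()`; the batched fitting kernel instead nudges the
colliding rate by a relative 1e-7, which perturbs the profile far below
any fitting-relevant tolerance and keeps the compiled loop branch-light.
A response is exactly zero at the instant of dosing; both paths pin that
value rather than leaving 1e-13-scale cancellation dust.

## Random effects and residual error

Individual parameters are log-normal around the typical values,
P_i = theta_P exp(eta_P,i), eta_i ~ N(0, Omega). The final DEX model
carries etas on CL/F, ka_IM and ka_PO (the central-volume variance
estimated near zero and is omitted — omitting a parameter from the eta
map is this package's way of "fixing a variance to zero", since a
singular Omega cannot enter the Laplace machinery). The final BET model
carries etas on CL/F, Vp/F, ka_IM, ka_IMa, ka_PO, Fr and Fra, with one
covariance term between CL/F and Vp/F. Observed log concentrations get
additive normal residual error with constant variance sigma^2; because
sigma does not depend on eta, the "with interaction" refinement of the
estimator coincides with plain Laplace here.

## Likelihood and censoring

Quantified records contribute the normal density of the log-scale
residual. Records below the 0.1 ng/mL limit contribute the censored
probability Phi((log LLOQ - log Cp)/sigma) — the M3 convention — with
`log_ndtr` used throughout so far-tail censoring (e.g. true pre-dose
zeros) stays finite. Model predictions are clamped at 1e-12 ng/mL before
logging; this only matters for samples drawn before a subject's first
dose of a drug, which are censored with probability one.

Each subject's marginal likelihood is the Laplace approximation: an
inner search finds the mode of the joint log-likelihood in eta, and the
marginal is the joint value at the mode plus (d/2) log 2pi minus half
the log-determinant of the negative Hessian there. The Hessian in that
correction is always the exact joint-log-likelihood Hessian by central
finite differences (step 1e-3 per eta component). The inner search is a
damped Newton ascent, batched across subjects: the search direction uses
the Gauss-Newton curvature (exact second derivatives for the censored
terms, first-order sensitivities for the prediction), switching to the
exact finite-difference Hessian near the mode where Gauss-Newton's tail
convergence is only linear. Steps are capped at 10 log-units and halved
until the joint log-likelihood does not decrease; a subject whose
gradient cannot be brought below tolerance is flagged, never dropped.
The public single-subject entry point starts the ascent at eta = 0 with
gradient tolerance 1e-8 (reproducibility over speed); the fitting path
uses 1e-6, below which the finite-difference noise floor of the
sensitivities makes further polishing meaningless (the induced objective
error is second order, ~1e-9 OFV units). Warm starts inherited across
objective evaluations are compared per subject against the eta = 0 start
and the better one is used, which prevents a poor trial point from
poisoning later mode searches.

On the fixture suite of 1- and 2-eta toys (small-IIV subjects, a
log-linear bioavailability toy where the marginal is exactly Gaussian,
and a censored-record toy) the Laplace value agrees with adaptive
quadrature within 1e-4 OFV units; the approximation error grows with
Omega (about 1e-4 per subject in loglik at omega^2 = 5e-4 for sparse
two-point designs), which is inherent to Laplace, not a defect of the
implementation.

## Population fitting

The objective is the OFV, -2 times the summed marginal log-likelihood
(all additive constants included; only differences are meaningful, and
nested-model differences are referred to a chi-square — the
likelihood-ratio test). The search space is log typical values, a
log-Cholesky factor per Omega block (a 2x2 block for the BET CL-Vp pair,
scalars elsewhere), and log sigma^2, bounded generously (|log theta| <=
8; log-SD in [-5, 3], below which a random effect is numerically
degenerate). L-BFGS-B drives the outer search with forward-difference
gradients (step 1e-5); all perturbed population points of a gradient are
evaluated in one stacked pass that replicates the subjects along a
virtual-subject axis, so the inner mode searches for every perturbation
run in a single vectorized batch. Convergence: relative objective change
below 1e-9 or projected gradient below 5e-3 — at the observed curvature
scale the latter bounds the typical-value error by well under 0.1%.

Starting values are data-driven unless supplied: clearance from
dose/AUC of the median IM-solution profile (tail-extrapolated), the
terminal volume from CL/lambda_z split 10:1 central:peripheral,
absorption rates from observed peak times, Fr from the oral:IM AUC
ratio, the acetate rate from the late slope of the suspension profile,
and generic moderate variances (0.1; residual 0.05). These are crude on
purpose; the fit carries the inference.

Standard errors come from the numerically differentiated OFV Hessian at
the optimum (central second differences on the diagonal, forward cross
differences off it — exact for quadratic objectives and adequate for a
covariance step; step 1e-3), cov = 2 H^-1, mapped by the delta method
through the log / log-Cholesky transform to the natural scale;
%RSE = 100 SE / |estimate|. A non-positive-definite or numerically
singular Hessian is an explicit failure flag, never a silent
pseudo-inverse. Reported CV% for a log-normal variance is
100 sqrt(exp(omega^2) - 1); the parenthesized value on a covariance row
is the implied correlation, not a CV.

## Synthetic study generator

No clinical data are distributed with this analysis, so the generator
reproduces the trial structure exactly and serves as the test bed for
every downstream stage: 48 women in eight crossover sequences (AB, BA,
CD, DC, ED, DE, CE, EC) of six; treatments A-E all delivering 6 mg free
alcohol equivalent (A: DEX-P IM; B: BET-P IM; C: BET-PA IM split 3 mg
phosphate + 3 mg acetate; D: DEX-P PO; E: BET-P PO); 17 samples per
period at 0 (pre-dose), 0.5, 1, 1.5, 2, 3, 4, 6, 12, 18, 24, 30, 36,
48, 60, 72 and 96 h post-dose; LLOQ 0.1 ng/mL. The period-2 dose falls
336 h after the first (4 days of sampling plus the 10-day washout);
this default is corroborated by the carryover check below. Body weight
is uniform on the reported 47.0-68.7 kg range and is a label only — no
covariate enters the model, mirroring the near-zero weight-clearance
correlation in the source population. Etas are drawn once per subject
per drug from the published Omegas (lower-triangular factor, so the
clearance coupling knob below acts on the intended component);
log-normal residual noise is applied per sample; values below the LLOQ
are flagged censored with the numeric value withheld (the latent value
survives in a hidden column for test oracles only). All randomness flows
from a single integer seed in a fixed draw order; equal seeds give
byte-identical datasets.

Subjects in sequences CE and EC receive BET in both periods, so their
BET history lives on one common clock with two dose events — the only
subjects for whom the time origin matters, because BET-PA's acetate
depot outlasts the washout. At the published typical values the BET-PA
prediction 336 h post-dose is 0.335 ng/mL, inside the 0.25-0.45 ng/mL
band implied by the residual pre-dose concentrations reported for the
second period (0.35 +/- 0.1 ng/mL). For any other sequence the two
periods involve different drugs and the per-drug histories are
single-dose, where the likelihood is shift-invariant.

What the generator does not emulate: sample-level missingness and
exclusions (the real study lost ~5-7% of possible observations; the
synthetic design is complete, and it retains pre-dose records, so its
censored fractions run somewhat above the trial's reported BLQ counts),
assay-error structure beyond the log-normal residual, occasion effects,
and any demographic covariate influence. Passing recovery tests
therefore demonstrate estimator correctness under the stated model, not
robustness to real-data pathologies.

A knob exists to correlate the two drugs' clearance etas within a
subject (a Gaussian coupling of the underlying normals; default off)
for sensitivity work on the cross-drug clearance comparison.

## Secondary descriptors and reporting conventions

Cmax and tmax are read off an hourly simulated grid up to 96 h (the
study's reporting convention; ties to the earliest time; a finer grid is
available). AUC uses exact per-exponential integration for model
profiles and the trapezoid rule otherwise; single-dose AUC to infinity
reduces to absorbed dose over CL/F. The terminal half-life is the
two-point convention ln 2 / ln(Cp(95)/Cp(96)); a profile not in decline
over that window raises an explicit "undefined" error rather than
returning a number. MRT is disposition residence time plus mean
absorption time, (Vss/F)/(CL/F) + 1/ka — the as-printed identity in the
source analysis subtracts 1/ka from the reciprocal ratio, which is
dimensionally inconsistent, so the corrected form is the default and
the literal one survives behind a `literal=True` flag for comparison.
For BET-PA the absorption rate is the absorbed-fraction-weighted
harmonic mean over the two depots with weights (1, Fra) — both
F_IM-relative; the variant weighting the phosphate depot by Fr (which
plays no role in IM dosing) is deliberately not adopted. MAT at the
published values is 71.1 h, and the 95-96 h half-life of the typical
BET-PA profile is 93.3 h: the acetate depot, not disposition (20.7 h),
controls the tail — flip-flop kinetics.

The orthogonal (total least squares) clearance comparison takes the
principal axis of the 2x2 scatter covariance through the centroid,
which minimizes summed squared perpendicular distances and is symmetric
under swapping the axes (slope -> 1/slope); r^2 is the squared Pearson
correlation.

## VPC and regimen simulation

The visual predictive check replicates the observed design (every
subject's dose events and sampling times) under candidate population
parameters — 500 replicates by default, one seeded stream — and bins at
the nominal sampling times within each treatment group. Observed and
simulated values below the LLOQ enter percentile computation as LLOQ/2
with the censored fraction reported per bin; a percentile that itself
falls below the LLOQ is reported as not numerically identified (NaN)
rather than as an imputation artifact, and an all-censored bin has no
numeric percentiles at all. Bands are the 2.5-97.5 percentile range of
each simulated percentile. Self-consistency (data simulated from the
fitted model should sit inside its own bands ~95% of the time) is the
acceptance check.

Regimen simulation superposes the WHO antenatal schedules — DEX-P 6 mg
IM every 12 h x4, BET-P 12 mg IM every 24 h x2, BET-PA 12 mg IM every
24 h x2 (split phosphate/acetate) — over 200 simulated subjects,
inter-individual variability only by default (residual error behind a
switch, since a band of measurement noise describes assay replicates,
not biology). Reported metrics: grid Cmax and its time, trough at the
end of the final dosing interval, AUC to the horizon (last dose + 336 h)
and to infinity (exact). At typical values the equal-total-dose AUC
ratio of BET-P to DEX-P is exactly the inverse clearance ratio,
9.29/5.95 = 1.56. One caveat this package's own arithmetic makes
explicit: with a 20.7 h disposition half-life, the BET-P regimen's
plasma concentrations stay above the 0.1 ng/mL quantification limit
until roughly 150 h (about 127 h after its last dose) — "eliminated
within about three days" is accurate only as an order-of-magnitude
statement, while DEX-P genuinely falls below the limit within ~57 h of
its last dose and BET-PA persists beyond 700 h.

## Problem sizes and protocols used by the checks

The parameter-recovery study simulates the complete 48-subject design
and fits it: one fully converged fit per drug from the data-driven
starts (the headline recovery check), plus a 20-replicate
simulation-estimation study in which replicates start at the generating
values under a fixed iteration budget (100 L-BFGS iterations for DEX,
30 for BET) — the usual protocol for such studies; the capped BET
optimum was verified to sit within 0.3 percentage points of the fully
converged one. Wald coverage uses the covariance step per replicate.
The oracle-equivalence checks use 1000 random draws (ODE) and the
fixture toy suite (quadrature); the VPC check uses 500 replicates of the
full design. These sizes are the package's defaults for its own
validation and all complete on a single CPU in well under half an hour.

## Known limitations

* Laplace, like any second-order approximation, is biased for sparse
  designs with large IIV; the study design here is dense (17 samples per
  period), which is why recovery is clean. No FOCE/SAEM alternative is
  provided.
* Inter-occasion variability is out of scope (the LRT machinery used to
  judge it is included; the model variant is not).
* The generator draws complete data; missingness mechanisms, dropout and
  covariate effects are not modeled.
* Estimates are apparent (F_IM-referenced) by construction; nothing in
  the package can or does recover absolute bioavailability.
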