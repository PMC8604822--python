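# Methods

## The models

Each endpoint of the sugar/fat preference test (SFPT) — sweetness,
creaminess, pleasantness, every solution rated 1–9 — is modeled as a
cumulative-logit mixed-effects model. The log-odds that subject *i* scores
at least *k* on an endpoint is

    L_k = alpha_1 + sum_{x=2}^{k-1} alpha_{x->x+1} + g_k(covariates) + eta_i (+ kappa_{i,occ})

where `alpha_1` is the logit of scoring above 1 (the anchor), the
increments `alpha_{x->x+1}` are nonpositive (so the cumulative logits are
nonincreasing in *k*), `eta_i ~ N(0, omega^2)` is a subject-level baseline,
and `kappa` is an optional occasion-level (inter-occasion variability)
effect, off by default. Category probabilities come from differencing the
logistic CDF across the `L_k`.

Sweetness and creaminess are proportional-odds models (one `g` for all
categories):

    g_S = Sugar * Smax_Sugar,i / (Sugar + SSugar50) + SL_S_Fat * Fat
    g_C = SL_C_Fat * Fat + SL_C_Sugar * Sugar

with between-subject variability on the sweetness ceiling,
`Smax_Sugar,i = Smax_Sugar * exp(eta_Smax)`. The multiplicative-exponential
form is our choice (it keeps the ceiling positive); an additive form is
available via `re_form="additive"`.

Pleasantness is a differential-odds model: the two driver terms of

    g_k = f(A) * betaA_k + f(B) * betaB_k + Int(A, B)

are scaled by category-range multipliers — the A-term (sugar or sweet
odds) by `beta_Sugar5` from k >= 5, the B-term (fat or cream odds) by
`beta_Fat3` from k >= 3, additionally `beta_Fat4` from k >= 4 and
`beta_Fat7` from k >= 7; the interaction term carries no multiplier. With
all betas at 1 the model collapses to proportional odds (tested exactly).
`f` is the shared saturating kernel `x * Emax / (x + x50)`, and
`Int(A,B) = IP * (wIP * A / cA + B / cB)` with fixed rescale constants:
the design maxima (20 %w sugar, 37.5 %w fat) in the amounts variant and
10,000 in the linked (odds) variant.

Driver variants for pleasantness:

- `amounts` — A, B are the solution's sugar and fat content;
- `linked` — A, B are the subject's predicted odds of scoring > 1 on
  sweetness/creaminess: `exp(alpha_1 + eta_base + g)`, recomputed from the
  current random effects inside every likelihood evaluation;
- `observed_scores` — the subject's observed sweetness/creaminess scores
  fed through the same kernels (rescale constant 9, the scale maximum; the
  published account does not print this form, so the rescale is our
  reading of the "rescale by the maximum" rule);
- `score_link` — the probability-weighted expected score
  `I_pred = sum_k k * p_k` of each driver submodel, rescale constant 9.

## Negative category mass under differential odds

A differential-odds model can make `L_k` locally increasing in *k*, i.e. a
negative category probability. This is not a pathological corner here: at
the packaged linked-model reference estimates (`beta_Fat3 = 3.3`), p6 is
slightly negative (up to 0.046) in 14 of 16 design cells for the typical
subject. We therefore define the model as the *rectified* distribution:
probabilities are floored at 1e-10 and renormalized, identically in the
simulator and in the likelihood, so the estimator remains maximum
likelihood for the generative process and recovery at the truth is
unbiased by construction. The per-evaluation floored mass is still
reported, and `ModelSpec.violation_penalty` (default 0) can add a penalty
of `penalty * mass` to the OFV for users who want to steer fits away from
grossly non-monotone regions.

## Estimation

The marginal likelihood integrates each subject's categorical likelihood
over its random effects (up to 4 subject-level dimensions in a joint
linked fit). We use a Laplace approximation: an inner Newton search with
central finite-difference gradients/Hessians (step 1e-4) finds the
conditional mode (the empirical Bayes estimate); the value plus the
log-determinant correction of the curvature gives the marginal term.
Subjects are evaluated batched on padded record matrices purely for speed;
results equal the per-subject definition (tested against a term-by-term
brute-force oracle). The inner search stops at gradient norm 1e-6 (1e-8 is
below finite-difference noise) or when no subject can improve further —
the rectified likelihood has rare near-kink regions at which a subject's
mode can carry a small residual gradient (< 0.05, costing well under 1e-3
in log-likelihood).

The log-determinant uses the **expected (Fisher) information** of the
conditional density at the mode, `I = sum_records sum_k p_k *
(dlogp_k)(dlogp_k)' + prior precision`, rather than the observed
finite-difference curvature. The expectation over scores is smooth in the
random effects and in the population parameters and positive definite by
construction; the observed curvature of the rectified likelihood
fluctuates violently where a category probability crosses its floor, which
would make the OFV locally rough and every covariance step of a joint
linked fit fragile. The residual non-positive-definite cases (numerical)
are repaired by eigenvalue clipping — a continuous correction, unlike an
escalating ridge.

An adaptive Gauss–Hermite quadrature (AGQ) routine, centered at the mode
and scaled by the same curvature, serves as the independent oracle for RE
dimension <= 2; `AGQ(1)` equals the Laplace value by construction, and AGQ
itself was validated against direct adaptive integration (agreement
~1e-12). Measured accuracy at the default design (32 observations per
subject, published variances): |Laplace − AGQ(41)| is below ~0.15 per
subject, of which ~1e-2 is the genuine second-order error of the skewed
ordinal likelihood and the remainder the expected-vs-observed information
difference; both shrink with per-subject information. This mirrors (and
somewhat exceeds) the approximation behavior of LAPLACE estimation in
standard pharmacometric tools — the price paid for a smooth, always-defined
marginal.

The outer problem minimizes `OFV = -2 sum_i log L_i` by L-BFGS-B on a
transformed scale — log for variances and half-max constants, `-exp(theta)`
for cutpoint increments (keeping them negative), identity otherwise — with
finite-difference gradients (step 1e-5), relative OFV tolerance 1e-9 and
projected-gradient tolerance 1e-4. Inner modes are warm-started across
outer evaluations. There is no randomness anywhere in fitting. Standard
errors come from the central finite-difference Hessian of OFV/2 at the
optimum, inverted and mapped to the natural scale by the delta method;
`RSE% = 100 * SE / |estimate|`. During this covariance step the inner
search restarts from the optimum's modes with a small step cap (so the
tracked conditional mode stays in one basin across the stencil — the
linked model's conditional posteriors can be multimodal), and the step per
parameter widens adaptively (from 5e-3 up to 0.5, relative) until the
second difference clears a signal floor: near-flat directions such as a
saturated half-max constant carry curvature of order 1e-3 that is
unresolvable at the nominal step, and the marginal can carry small
mode-fold kinks, so the reported curvature is the one resolvable at the
chosen scale. When the resulting Hessian is still not positive definite,
SEs are reported as unavailable rather than fabricated.
`AIC = OFV + 2 * n_estimated`; nested fits are compared by a chi-square
likelihood-ratio test at significance 0.01 by default, and the comparison
report notes when equal parameter counts reduce the AIC comparison to the
OFV comparison.

## Linking approaches

- **SIM** — one joint fit of all three endpoints; the subject's RE vector
  spans all active components and the pleasantness drivers are recomputed
  from the current eta inside every conditional evaluation.
- **PPP&D** — driver population parameters fixed at stage-1 estimates, but
  the driver *data* stay in the joint likelihood, so the driver REs remain
  informed by their own scores during pleasantness estimation.
- **IPP** — stage-1 EBEs (computed from driver data only) give per-record
  predicted odds written as frozen covariates; stage 2 fits pleasantness
  alone with a 1-D random effect. Stage-1 uncertainty is not propagated
  into stage-2 SEs (the known limitation of IPP).

Stage 1 fits sweetness and creaminess jointly; they share no parameters,
so this equals two separate fits and exists for a single code path. With
all driver variances at zero, IPP and PPP&D stage-2 likelihoods are
identical (tested).

## Synthetic studies

`StudyConfig` defaults reproduce the original design: 64 subjects, 48%
male (deterministic count, round(n * fraction)), three BMI strata in equal
thirds by largest-remainder rounding (the strata sizes were not published;
the proportions are config-overridable), uniform BMI within band — lean
18.5–25, obese 30–35, very obese 35–45 (the upper cap is arbitrary and
exposed), no subject in the overweight band 25–30 — two occasions, and the
4 x 4 factorial of fat {0, 3.5, 11.3, 37.5} and sugar {0, 5, 10, 20} %w/w
presented in an independent random order per (subject, occasion). One
master seed drives fixed sub-streams (population, per-subject designs,
random effects, scores), so partial reruns reproduce exactly. Simulated
scores are drawn from the exact model probabilities, including, in the
linked variant, pleasantness driven by the same subject's etas through the
individual odds.

The generator emulates the design and the generative models only: no
rating drift, order effects, dropout, covariate effects of sex or BMI on
the scores, or between-endpoint random-effect correlation (the published
variance table reports no covariances, and the random effects are
independent here). Tests passing on this generator show estimator and
pipeline correctness under the stated model — not robustness to the
misspecifications real rating data may carry.

## Problem sizes and numerical choices in the test and acceptance suites

Everything runs on one CPU. Sizes were chosen so the full suite stays
within desk scale:

- Recovery experiments (linked and amounts variants) use the full default
  design (64 subjects) and 10 replicates, starting fits at the truth — the
  standard simulation–estimation convention, so bias is attributable to
  the estimator rather than search failures. The acceptance script refits
  the complete pleasantness submodel (19 parameters) with a relative OFV
  tolerance of 1e-7, ample for variance estimates quoted to two digits.
- The three-approach comparison runs at 16 subjects with cutpoints held at
  their true values: SIM frees the structural driver parameters (Emax,
  half-max, slopes and the two driver variances) plus the 7 pleasantness
  parameters, while the sequential approaches fix the driver parameters at
  stage-1 estimates of the same set. This preserves exactly the contrast
  the approaches embody (whether driver-parameter uncertainty propagates)
  at tractable cost. The fat slope on sweetness (true value 0.0033 logit
  per %w — essentially null) is held at its true value throughout: at this
  size it carries no information and only destabilizes the covariance
  step.
- VPC calibration uses 200 replicates; the production default is 1000.
  Bins are the exact design levels (4 sugar or 4 fat bins), occasions
  pooled, and the 95% band is the empirical 2.5/97.5 percentile across
  replicates (linear interpolation).

## Known limitations

- SEs are Hessian-based; tools that combine score and Hessian information
  (R/S "sandwich" matrices) can report somewhat different RSEs.
- No analytic gradients; finite differences are the main performance
  lever left.
- AGQ oracle is limited to 2 random-effect dimensions (tensor grids grow
  too fast beyond that); joint linked fits rely on Laplace alone.
- IOV (occasion-level kappa) is implemented but off by default and only
  lightly exercised.
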