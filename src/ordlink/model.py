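"""Deterministic model mathematics for the three ordinal endpoints.

Every endpoint is a cumulative-logit model on the 9-point score scale.  The
log-odds of ``score >= k`` is an anchor (the logit of score > 1) plus a sum
of nonpositive increments, shifted by a covariate function ``g`` and a
subject-level random baseline:

    L_k = alpha_1 + sum_{x=2}^{k-1} alpha_{x->x+1} + g_k + eta (+ kappa)

Sweetness and creaminess are proportional-odds models (``g`` identical for
every k).  Pleasantness is a differential-odds model: the sugar/sweet and
fat/cream terms of ``g_k`` are multiplied by score-range-specific ``beta``
factors, so covariates may act unequally across categories.  With all betas
equal to 1 the differential model collapses to proportional odds.

The pleasantness driver comes in four variants:

- ``amounts``: sugar and fat content of the solution (%w/w),
- ``linked``: each subject's predicted odds of sweetness/creaminess > 1,
- ``observed_scores``: the subject's observed sweetness/creaminess scores,
- ``score_link``: the probability-weighted expected score (I_pred).

All functions are pure and broadcast over numpy arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.special import expit

from .data import (
    ParameterSet,
    Solution,
    ValidationError,
    pleasantness_link_names,
)

#: fixed rescale denominators for the interaction term, by variant
SUGAR_MAX = 20.0
FAT_MAX = 37.5
ODDS_RESCALE = 10_000.0
SCORE_RESCALE = 9.0

#: probability floor under differential-odds monotonicity violations
PROB_FLOOR = 1e-10
#: width of the smooth-max used to apply the floor.  A hard max would put a
#: first-derivative kink in the log-likelihood wherever a category
#: probability crosses zero; near such a point the curvature (and with it
#: the Laplace log-determinant) becomes unbounded and discontinuous.  The
#: smooth rectification bounds the curvature while perturbing probabilities
#: away from the crossing by at most ~SMOOTH^2/(4p).
RECT_SMOOTH = 1e-4


def rectify_probabilities(p: np.ndarray):
    """Smoothly floor a (possibly invalid) category-probability vector and
    renormalize; returns (p_rectified, floored_mass).

    Used identically by the simulator and the likelihood, so the rectified
    distribution *is* the model and maximum likelihood at the generating
    values stays consistent.
    """
    floored_mass = np.clip(-p, 0.0, None).sum(axis=-1)
    p = 0.5 * (p + PROB_FLOOR + np.sqrt((p - PROB_FLOOR) ** 2 + RECT_SMOOTH ** 2))
    p = p / p.sum(axis=-1, keepdims=True)
    return p, floored_mass

_CUT_PREFIX = {"sweetness": "S", "creaminess": "C", "pleasantness": "P"}


@dataclass
class RandomEffectVector:
    """Per-subject latent deviations (logit units); all-zero = typical subject."""

    eta_S_base: float = 0.0
    eta_Smax: float = 0.0
    eta_C_base: float = 0.0
    eta_P_base: float = 0.0
    #: optional occasion effects, keyed by (endpoint, occasion)
    kappa: dict = field(default_factory=dict)


class CategoryProbabilities(NamedTuple):
    """Probabilities of scores 1..9 plus a monotonicity-violation flag.

    ``floored_mass`` is the total negative probability mass that had to be
    floored away (nonzero only when a differential-odds g-vector crosses the
    cumulative logits); estimators penalize it rather than raising.
    """

    p: np.ndarray
    floored_mass: np.ndarray
    violated: np.ndarray


def _get(params, name):
    return params[name]


def _check_nonneg(**kv):
    for name, v in kv.items():
        if np.any(np.asarray(v) < 0):
            raise ValidationError(f"{name} must be nonnegative")


# --------------------------------------------------------------------------
# covariate functions
# --------------------------------------------------------------------------

def emax_effect(x, emax, x50):
    """Saturating effect ``x * emax / (x + x50)``; the shared kernel of every
    maximal-effect covariate relationship (sugar, fat, sweet odds, cream odds)."""
    if np.any(np.asarray(x50) <= 0):
        raise ValidationError(f"x50 must be > 0, got {x50}")
    x = np.asarray(x, dtype=float)
    return x * emax / (x + x50)


def g_sweetness(sugar, fat, params, eta_Smax=0.0, re_form: str = "exponential"):
    """Logit-scale sweetness effect: saturating in sugar, linear in fat.

    Between-subject variability acts on the sugar ceiling; ``re_form``
    selects multiplicative-exponential (default, keeps the ceiling positive)
    or additive.
    """
    _check_nonneg(sugar=sugar, fat=fat)
    smax = _get(params, "Smax_Sugar")
    if re_form == "exponential":
        smax_i = smax * np.exp(eta_Smax)
    elif re_form == "additive":
        smax_i = smax + eta_Smax
    else:
        raise ValidationError(f"unknown re_form {re_form!r}")
    return emax_effect(sugar, smax_i, _get(params, "SSugar50")) + _get(params, "SL_S_Fat") * np.asarray(fat, float)


def g_creaminess(sugar, fat, params):
    """Logit-scale creaminess effect: linear in both fat and sugar."""
    _check_nonneg(sugar=sugar, fat=fat)
    return _get(params, "SL_C_Fat") * np.asarray(fat, float) + _get(params, "SL_C_Sugar") * np.asarray(sugar, float)


def interaction_amounts(sugar, fat, params):
    """Apparent sugar-fat interaction, amounts rescaled by the design maxima
    (20 %w sugar, 37.5 %w fat)."""
    _check_nonneg(sugar=sugar, fat=fat)
    return _get(params, "IP_Sugar_Fat") * (
        _get(params, "wIP_Sugar") * np.asarray(sugar, float) / SUGAR_MAX
        + np.asarray(fat, float) / FAT_MAX
    )


def interaction_linked(odds_sweet, odds_cream, params):
    """Apparent sweet-cream interaction; the individual odds are rescaled by
    the fixed constant 10,000."""
    _check_nonneg(odds_sweet=odds_sweet, odds_cream=odds_cream)
    return _get(params, "IP_Sweet_Cream") * (
        _get(params, "wIP_Sweet") * np.asarray(odds_sweet, float) / ODDS_RESCALE
        + np.asarray(odds_cream, float) / ODDS_RESCALE
    )


def individual_odds(endpoint: str, solution: Solution, params, etas: Optional[RandomEffectVector] = None,
                    re_form: str = "exponential"):
    """A subject's predicted odds of scoring > 1 on sweetness or creaminess.

    This is the exponential of the individual predicted log-odds of the
    cumulative probability of score > 1, i.e. ``p/(1-p)`` with
    ``p = P(score >= 2)`` -- the quantity that links the driver submodels to
    pleasantness in the linked variant.
    """
    etas = etas or RandomEffectVector()
    if endpoint == "sweetness":
        lin = params["alpha_S1"] + etas.eta_S_base + g_sweetness(
            solution.sugar, solution.fat, params, etas.eta_Smax, re_form)
    elif endpoint == "creaminess":
        lin = params["alpha_C1"] + etas.eta_C_base + g_creaminess(solution.sugar, solution.fat, params)
    else:
        raise ValidationError(f"individual odds defined for driver endpoints only, got {endpoint!r}")
    return np.exp(lin)


def beta_vectors(params):
    """(sugar/sweet, fat/cream) differential-odds multipliers for k = 2..9.

    The sugar/sweet term is multiplied by beta_Sugar5 from score >= 5 on; the
    fat/cream term accumulates beta_Fat3 (>= 3), beta_Fat4 (>= 4) and
    beta_Fat7 (>= 7).  The interaction term is never multiplied by a beta.
    """
    b5 = params["beta_Sugar5"]
    b3, b4, b7 = params["beta_Fat3"], params["beta_Fat4"], params["beta_Fat7"]
    beta_a = np.array([1.0, 1.0, 1.0, b5, b5, b5, b5, b5])
    beta_b = np.array([1.0, b3, b3 * b4, b3 * b4, b3 * b4, b3 * b4 * b7, b3 * b4 * b7, b3 * b4 * b7])
    return beta_a, beta_b


def _link_kernels(driver_a, driver_b, params, variant):
    """f(driver_a), f(driver_b), Int(driver_a, driver_b) for the pleasantness model."""
    names = pleasantness_link_names(variant)
    pmax_a, p50_a, pmax_b, p50_b, ip, wip = (params[n] for n in names)
    rescale_a, rescale_b = {
        "amounts": (SUGAR_MAX, FAT_MAX),
        "linked": (ODDS_RESCALE, ODDS_RESCALE),
        "observed_scores": (SCORE_RESCALE, SCORE_RESCALE),
        "score_link": (SCORE_RESCALE, SCORE_RESCALE),
    }[variant]
    da = np.asarray(driver_a, float)
    db = np.asarray(driver_b, float)
    fa = emax_effect(da, pmax_a, p50_a)
    fb = emax_effect(db, pmax_b, p50_b)
    inter = ip * (wip * da / rescale_a + db / rescale_b)
    return fa, fb, inter


def pleasantness_g_vector(driver_values, params, variant: str):
    """Differential-odds covariate vector g_k (k = 2..9) for pleasantness.

    ``driver_values`` is a pair: (sugar, fat) amounts, (odds_sweet,
    odds_cream), or (sweetness, creaminess) observed/expected scores,
    depending on ``variant``.  The kernels are identical across variants;
    only the inputs and the interaction rescale differ.
    """
    if variant not in ("amounts", "linked", "observed_scores", "score_link"):
        raise ValidationError(f"unknown variant {variant!r}")
    da, db = driver_values
    _check_nonneg(driver_a=da, driver_b=db)
    fa, fb, inter = _link_kernels(da, db, params, variant)
    beta_a, beta_b = beta_vectors(params)
    return (np.asarray(fa)[..., None] * beta_a
            + np.asarray(fb)[..., None] * beta_b
            + np.asarray(inter)[..., None])


# --------------------------------------------------------------------------
# cumulative logits and probabilities
# --------------------------------------------------------------------------

def cutpoint_base(params, endpoint: str) -> np.ndarray:
    """Baseline cumulative logits (anchor + partial increment sums), k = 2..9."""
    prefix = _CUT_PREFIX[endpoint]
    anchor = params[f"alpha_{prefix}1"]
    incs = np.array([params[f"alpha_{prefix}{x}_{x + 1}"] for x in range(2, 9)])
    return anchor + np.concatenate([[0.0], np.cumsum(incs)])


def cumulative_logits(params, endpoint: str, g=0.0, eta_base=0.0, kappa=0.0) -> np.ndarray:
    """Cumulative log-odds L_k of score >= k for k = 2..9.

    ``g`` is a scalar (proportional odds) or an array whose last axis has
    length 8 (differential odds).  ``eta_base`` and ``kappa`` are additive
    subject- and occasion-level shifts.
    """
    base = cutpoint_base(params, endpoint)
    g = np.asarray(g, float)
    if g.ndim == 0 or g.shape[-1] != 8:
        g = g[..., None]
    shift = np.asarray(eta_base, float)[..., None] + np.asarray(kappa, float)[..., None]
    return base + g + shift


def category_probabilities(L) -> CategoryProbabilities:
    """Difference the cumulative distribution into per-score probabilities.

    ``p_1 = 1 - sigma(L_2)``, ``p_k = sigma(L_k) - sigma(L_{k+1})``,
    ``p_9 = sigma(L_9)``.  Differential-odds settings can make some p_k
    negative; those are floored at 1e-10 and the vector renormalized, with
    the floored mass reported so estimators can penalize instead of failing.
    """
    L = np.asarray(L, float)
    if L.shape[-1] != 8:
        raise ValidationError("expected 8 cumulative logits (k = 2..9)")
    c = expit(L)
    shape = L.shape[:-1]
    p = np.concatenate(
        [1.0 - c[..., :1], c[..., :-1] - c[..., 1:], c[..., -1:]], axis=-1)
    p, floored_mass = rectify_probabilities(p)
    violated = floored_mass > 0
    return CategoryProbabilities(p=p, floored_mass=np.asarray(floored_mass).reshape(shape),
                                 violated=np.asarray(violated).reshape(shape))


def ipred_score(p):
    """Probability-weighted expected score, sum_k p_k * k (in [1, 9])."""
    if isinstance(p, CategoryProbabilities):
        p = p.p
    p = np.asarray(p, float)
    return p @ np.arange(1, 10)


def observation_loglik(score, p):
    """Log-probability of an observed score given a category distribution.

    When the distribution was floored/renormalized, this is the log of the
    penalized (renormalized) probability.
    """
    if isinstance(p, CategoryProbabilities):
        p = p.p
    p = np.asarray(p, float)
    score = np.asarray(score)
    if np.any((score < 1) | (score > 9)):
        raise ValidationError("score must be in 1..9")
    idx = np.asarray(score, int) - 1
    return np.log(np.take_along_axis(p, idx[..., None], axis=-1)[..., 0]
                  if p.ndim > 1 else p[idx])
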