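"""Likelihood and priors of the hierarchical transition model.

Adult fates follow a multinomial whose cell probabilities factor into a
logit-linear mortality and two conditional Bernoulli choices (reproduce?
large?).  Seedling and juvenile 13-month fates follow a conditional chain
of survive -> progress -> which stage.  Recruit counts are Poisson with
mean proportional to the interval's fruit-weighted adult exposure.

Priors mirror a deliberately vague specification: Uniform(0, 1) on every
probability, Normal(0, 1000^2) on regression coefficients, Normal(0,
sigma_month^2) on the monthly random effects with sigma_month ~
Uniform(0, 10) per stream, and Uniform(0, 10) on the recruitment rates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, xlogy

from .census import TransitionCounts
from .params import RHO, HierParams
from .stages import ADULT_INDEX

__all__ = [
    "adult_mortality",
    "adult_fate_probs",
    "young_fate_probs",
    "recruit_mean",
    "log_likelihood",
    "log_prior",
    "adult_fate_array",
    "monthly_kernel",
]

_LOG_COEF_SD = 1000.0
_SIGMA_UPPER = 10.0
_F_UPPER = 10.0


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

def adult_mortality(params: HierParams, stage, month: int, population: int) -> float:
    """Monthly death probability of an adult (stage code or index; 0-based pop)."""
    i = ADULT_INDEX[stage] if isinstance(stage, str) else int(stage)
    if not 0 <= i < 3:
        raise IndexError(f"adult stage index {i} out of range")
    if not 0 <= population < params.n_populations:
        raise IndexError(f"population index {population} out of range")
    if not 0 <= month < params.n_transition_months:
        raise IndexError(f"month index {month} out of range")
    q = params.stream_map[population]
    logit = (params.stage_effect[i] + params.month_effect[q, month]
             + params.pop_effect[population])
    return float(expit(logit))


def adult_fate_probs(m, r, s) -> np.ndarray:
    """Monthly fate distribution of a live adult over (A0, A1, A2, D).

    ``m`` is mortality; given survival the adult reproduces with
    probability ``r``; given reproduction it is large with probability
    ``s``.  Broadcasts; the fate axis is appended last.
    """
    m, r, s = np.broadcast_arrays(*(np.asarray(x, float) for x in (m, r, s)))
    surv = 1.0 - m
    return np.stack(
        [surv * (1.0 - r), surv * r * (1.0 - s), surv * r * s, m], axis=-1
    )


def adult_fate_array(params: HierParams) -> np.ndarray:
    """Fate probabilities for every (population, month, stage): (K, M, 3, 4)."""
    logits = (
        params.stage_effect[None, None, :]
        + params.month_effect[params.stream_map][:, :, None]
        + params.pop_effect[:, None, None]
    )
    m = expit(logits)
    return adult_fate_probs(m, params.r[:, None, :], params.s[:, None, :])


def monthly_kernel(params: HierParams, population: int, month=None) -> np.ndarray:
    """4x4 column-stochastic monthly adult kernel over (A0, A1, A2, D).

    Columns are the starting stage.  ``month=None`` sets the monthly
    random effect to its central value 0 (used for projection); an
    integer month uses that month's realized effect.
    """
    if month is None:
        eff = 0.0
    else:
        eff = params.month_effect[params.stream_map[population], month]
    logits = params.stage_effect + eff + params.pop_effect[population]
    m = expit(logits)
    fates = adult_fate_probs(m, params.r[population], params.s[population])  # (3, 4)
    kernel = np.zeros((4, 4))
    kernel[:, :3] = fates.T
    kernel[3, 3] = 1.0  # dead individuals remain dead
    return kernel


def young_fate_probs(params: HierParams, stage: str, population: int) -> np.ndarray:
    """13-month fate distribution of a seedling or juvenile.

    Seedlings -> (S, J, A0, A1, D); juveniles -> (J, A0, A1, A2, D).
    Survival is population-specific (``a[k]``, offset ``b`` for
    juveniles); the progression chain is shared across populations.
    """
    if not 0 <= population < params.n_populations:
        raise IndexError(f"population index {population} out of range")
    if stage == "S":
        surv = expit(params.a[population])
        g, t1, t2 = params.g_y, params.t_sj, params.t_sn
    elif stage == "J":
        surv = expit(params.a[population] + params.b)
        g, t1, t2 = params.g_j, params.t_jn, params.t_js
    else:
        raise ValueError(f"young stage must be 'S' or 'J', got {stage!r}")
    stay = surv * (1.0 - g)
    adv = surv * g
    # seedling: stay, ->J, ->A0, ->A1, dead
    # juvenile: stay, ->A0, ->A1, ->A2, dead
    return np.array(
        [stay, adv * t1, adv * (1.0 - t1) * t2, adv * (1.0 - t1) * (1.0 - t2),
         1.0 - surv]
    )


def recruit_mean(params: HierParams, exposure: float, population: int = 0):
    """Expected (new seedlings, new juveniles) for a given adult exposure.

    ``exposure`` is in small-reproductive-adult-equivalent months (an A2
    month counts ``RHO`` = 7.8 times an A1 month).
    """
    if exposure < 0:
        raise ValueError("exposure must be nonnegative")
    total = params.f[population] * exposure
    return params.phi * total, (1.0 - params.phi) * total


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _multinomial_logpmf(n: np.ndarray, p: np.ndarray) -> float:
    """Sum of multinomial log-pmfs along the last axis."""
    n = np.asarray(n, float)
    coef = gammaln(n.sum(axis=-1) + 1.0) - gammaln(n + 1.0).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(n, p).sum(axis=-1)
    return float((coef + ll).sum())


def _poisson_logpmf(n: float, mu: float) -> float:
    if mu == 0.0:
        return 0.0 if n == 0 else -np.inf
    return float(n * np.log(mu) - mu - gammaln(n + 1.0))


def gap_kernel(params: HierParams, population: int, month: int, gap: int) -> np.ndarray:
    """Product of ``gap`` monthly kernels starting at ``month``."""
    out = np.eye(4)
    for t in range(month, month + gap):
        out = monthly_kernel(params, population, t) @ out
    return out


def log_likelihood(params: HierParams, counts: TransitionCounts) -> float:
    """Joint log-likelihood of all tabulated counts under ``params``.

    Returns ``-inf`` (never raises) when a positive count sits on a
    zero-probability fate; empty counts give exactly 0.
    """
    total = 0.0
    # adult one-month strata
    if counts.adult1.any():
        probs = adult_fate_array(params)
        total += _multinomial_logpmf(counts.adult1, probs)
    # gap strata: g-step kernel products
    for (k, j, g), n in counts.adult_gaps.items():
        kern = gap_kernel(params, k, j, g)
        total += _multinomial_logpmf(np.asarray(n, float), kern[:, :3].T)
    # young 13-month strata
    for k in range(counts.n_populations):
        if counts.young_s[k].any():
            total += _multinomial_logpmf(
                counts.young_s[k], young_fate_probs(params, "S", k)
            )
        if counts.young_j[k].any():
            total += _multinomial_logpmf(
                counts.young_j[k], young_fate_probs(params, "J", k)
            )
    # recruits: independent Poisson counts per interval and stage
    for k, n_s, n_j, exposure in counts.recruits:
        mu_s, mu_j = recruit_mean(params, exposure, k)
        total += _poisson_logpmf(n_s, mu_s) + _poisson_logpmf(n_j, mu_j)
    return total


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _normal_logpdf(x, sd):
    x = np.asarray(x, float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - np.log(sd * np.sqrt(2.0 * np.pi))))


def log_prior(params: HierParams) -> float:
    """Joint log-prior density; -inf outside the support."""
    for name, value in params.probability_fields().items():
        arr = np.asarray(value, float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            return -np.inf
    if np.any(params.f < 0.0) or np.any(params.f > _F_UPPER):
        return -np.inf
    if np.any(params.sigma_month <= 0.0) or np.any(params.sigma_month > _SIGMA_UPPER):
        return -np.inf
    total = 0.0
    # Uniform(0,1) probabilities contribute 0; Uniform(0,10) rates and sigmas
    total += -np.log(_F_UPPER) * params.f.size
    total += -np.log(_SIGMA_UPPER) * params.sigma_month.size
    # vague normal priors on regression coefficients
    total += _normal_logpdf(params.stage_effect, _LOG_COEF_SD)
    total += _normal_logpdf(params.pop_effect[1:], _LOG_COEF_SD)
    total += _normal_logpdf(params.a, _LOG_COEF_SD)
    total += _normal_logpdf(params.b, _LOG_COEF_SD)
    # hierarchical month effects, stream-specific scale
    for q in range(2):
        total += _normal_logpdf(params.month_effect[q], params.sigma_month[q])
    return total
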