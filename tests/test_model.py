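"""Hierarchical model: fate probabilities, likelihood, priors."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

import orchidemog as od
from orchidemog.census import TransitionCounts

from conftest import single_pop_params

probs = st.floats(min_value=0.001, max_value=0.999)


def test_adult_mortality_closed_forms():
    p = single_pop_params(n_months=5, m=0.5)
    p.stage_effect[:] = 0.0
    assert od.adult_mortality(p, "A0", 0, 0) == pytest.approx(0.5)
    p.stage_effect[:] = -2.0
    assert od.adult_mortality(p, "A1", 1, 0) == pytest.approx(1 / (1 + math.e ** 2))


def test_adult_mortality_monotone_in_pop_effect():
    p = od.default_true_params()
    vals = []
    for eff in (-1.0, 0.0, 1.0, 2.0):
        p.pop_effect[2] = eff
        vals.append(od.adult_mortality(p, "A2", 3, 2))
    assert np.all(np.diff(vals) > 0)


def test_adult_mortality_rejects_bad_indices():
    p = od.default_true_params()
    with pytest.raises((IndexError, KeyError)):
        od.adult_mortality(p, "A7", 0, 0)
    with pytest.raises(IndexError):
        od.adult_mortality(p, "A0", 0, 99)


@pytest.mark.parametrize(
    "m,r,s,expected",
    [
        (0.2, 0.5, 0.4, (0.40, 0.24, 0.16, 0.20)),
        (1.0, 0.3, 0.9, (0.0, 0.0, 0.0, 1.0)),
        (0.0, 1.0, 1.0, (0.0, 0.0, 1.0, 0.0)),
    ],
)
def test_adult_fate_probs_decomposition(m, r, s, expected):
    np.testing.assert_allclose(od.adult_fate_probs(m, r, s), expected, atol=1e-12)


@given(m=probs, r=probs, s=probs)
@settings(derandomize=True, max_examples=60)
def test_adult_fate_probs_sum_to_one(m, r, s):
    assert od.adult_fate_probs(m, r, s).sum() == pytest.approx(1.0, abs=1e-12)


def test_young_fate_probs_chain_arithmetic():
    p = single_pop_params(n_months=5)
    p.a[0] = 0.0  # seedling survival 0.5
    p.g_y, p.t_sj, p.t_sn = 0.4, 0.75, 0.5
    np.testing.assert_allclose(
        od.young_fate_probs(p, "S", 0), [0.30, 0.15, 0.025, 0.025, 0.50], atol=1e-12
    )
    p.g_y = 0.0  # no progression: surviving mass stays S
    v = od.young_fate_probs(p, "S", 0)
    assert v[0] == pytest.approx(0.5) and v[1:4].sum() == 0


@given(a=st.floats(-3, 3), b=st.floats(-2, 2), g=probs, t1=probs, t2=probs)
@settings(derandomize=True, max_examples=60)
def test_young_fate_probs_sum_to_one(a, b, g, t1, t2):
    p = single_pop_params(n_months=5)
    p.a[0], p.b = a, b
    p.g_j, p.t_jn, p.t_js = g, t1, t2
    assert od.young_fate_probs(p, "J", 0).sum() == pytest.approx(1.0, abs=1e-12)


def test_recruit_mean_split_and_linearity():
    p = single_pop_params(n_months=5)
    p.f[0], p.phi = 0.1, 0.7
    assert od.recruit_mean(p, 0.0, 0) == (0.0, 0.0)
    mu_s, mu_j = od.recruit_mean(p, 10.0, 0)
    assert (mu_s, mu_j) == (pytest.approx(0.7), pytest.approx(0.3))
    mu_s2, mu_j2 = od.recruit_mean(p, 20.0, 0)
    assert mu_s2 == pytest.approx(2 * mu_s) and mu_j2 == pytest.approx(2 * mu_j)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _single_stratum_params():
    p = single_pop_params(n_months=3, r=0.5, s=0.4)
    p.stage_effect[:] = logit(0.2)  # mortality 0.2 for every stage
    return p


def test_loglik_empty_counts_is_zero():
    counts = TransitionCounts.empty(1, 2)
    p = _single_stratum_params()
    assert od.log_likelihood(p, counts) == 0.0


def test_loglik_single_observation():
    counts = TransitionCounts.empty(1, 2)
    counts.adult1[0, 0, 0] = [1, 0, 0, 0]  # one A0 stayed A0
    p = _single_stratum_params()  # fate probs (0.4, 0.24, 0.16, 0.2)
    assert od.log_likelihood(p, counts) == pytest.approx(math.log(0.4))


def test_loglik_matches_exhaustive_enumeration():
    """Three individuals in one stratum: enumerate every labelled outcome."""
    counts = TransitionCounts.empty(1, 2)
    target = np.array([1, 0, 2, 0])
    counts.adult1[0, 0, 1] = target
    p = _single_stratum_params()
    fate_p = od.adult_fate_probs(0.2, 0.5, 0.4)
    total = 0.0
    for assignment in itertools.product(range(4), repeat=3):
        if np.array_equal(np.bincount(assignment, minlength=4), target):
            total += math.prod(fate_p[i] for i in assignment)
    assert od.log_likelihood(p, counts) == pytest.approx(math.log(total))


def test_loglik_zero_probability_returns_neg_inf():
    counts = TransitionCounts.empty(1, 2)
    counts.adult1[0, 0, 0] = [0, 1, 0, 0]  # reproduced...
    p = _single_stratum_params()
    p.r[0, 0] = 0.0  # ...which the parameters forbid
    assert od.log_likelihood(p, counts) == -np.inf


def test_loglik_gap_stratum_uses_two_step_kernel():
    counts = TransitionCounts.empty(1, 3)
    counts.adult_gaps[(0, 0, 2)] = np.zeros((3, 4), dtype=int)
    counts.adult_gaps[(0, 0, 2)][0, 3] = 1  # A0, dead two months later
    p = _single_stratum_params()
    # P(dead within 2 months) = 1 - 0.8^2 under uniform survival 0.8
    assert od.log_likelihood(p, counts) == pytest.approx(math.log(1 - 0.8 ** 2))


def test_loglik_maximized_at_empirical_frequencies():
    counts = TransitionCounts.empty(1, 2)
    counts.adult1[0, 0, 0] = [40, 24, 16, 20]  # matches m=.2, r=.5, s=.4
    base = od.log_likelihood(_single_stratum_params(), counts)
    for dm, dr, ds in [(0.05, 0, 0), (-0.05, 0, 0), (0, 0.08, 0),
                       (0, -0.08, 0), (0, 0, 0.08), (0, 0, -0.08)]:
        p = single_pop_params(n_months=3, r=0.5 + dr, s=0.4 + ds)
        p.stage_effect[:] = logit(0.2 + dm)
        assert od.log_likelihood(p, counts) < base


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def test_prior_closed_form():
    p = single_pop_params(n_months=3)
    p.a[0] = 0.0
    p.b = 0.0
    p.stage_effect[:] = 0.0
    # probabilities contribute 0; coefficients at 0 contribute -ln(1000*sqrt(2pi))
    coef_term = -math.log(1000 * math.sqrt(2 * math.pi))
    n_coef = 3 + 0 + 1 + 1  # stage effects, free pop effects, a, b
    month_term = 2 * 2 * (-math.log(1e-9 * math.sqrt(2 * math.pi)))
    expected = (n_coef * coef_term + month_term
                - math.log(10)  # f ~ Uniform(0, 10)
                - 2 * math.log(10))  # sigma_month ~ Uniform(0, 10) per stream
    assert od.log_prior(p) == pytest.approx(expected)


def test_prior_out_of_range_probability_is_neg_inf():
    p = single_pop_params(n_months=3)
    p.t_sj = 1.2
    assert od.log_prior(p) == -np.inf
    p.t_sj = 0.5
    p.sigma_month[0] = 11.0
    assert od.log_prior(p) == -np.inf
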