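"""Eigen-statistics, posterior summaries and the stage-structure test."""

import numpy as np
import pytest

import orchidemog as od
from orchidemog import tables


def _power_iteration(A, tol=1e-14, max_iter=20000):
    x = np.full(A.shape[0], 1.0 / A.shape[0])
    lam = 0.0
    for _ in range(max_iter):
        y = A @ x
        new = np.linalg.norm(y)
        x = y / new
        if abs(new - lam) < tol:
            break
        lam = new
    return lam, x / x.sum()


def test_dominant_eigenvalue_closed_forms():
    assert od.dominant_eigenvalue(np.eye(3) * 0 + np.eye(3)) == pytest.approx(1.0)
    A = np.array([[0.0, 2.0], [0.5, 0.0]])
    assert od.dominant_eigenvalue(A) == pytest.approx(1.0)
    np.testing.assert_allclose(od.stable_stage(A), [2 / 3, 1 / 3], atol=1e-12)


def test_eigen_matches_power_iteration_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(100):
        A = rng.uniform(0.01, 1.0, size=(5, 5))
        lam, w = _power_iteration(A)
        assert od.dominant_eigenvalue(A) == pytest.approx(lam, abs=1e-10)
        np.testing.assert_allclose(od.stable_stage(A), w, atol=1e-8)


def test_stable_stage_satisfies_eigen_identity():
    A = tables.load_transition_matrix(1).entries
    lam = od.dominant_eigenvalue(A)
    w = od.stable_stage(A)
    np.testing.assert_allclose(A @ w, lam * w, atol=1e-10)
    assert w.sum() == pytest.approx(1.0) and np.all(w > 0)


@pytest.mark.parametrize("pop", tables.POPULATIONS)
def test_elasticities_sum_to_one_and_respect_zero_pattern(pop):
    A = tables.load_transition_matrix(pop).entries
    E = od.elasticity_matrix(A)
    assert E.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(E[A == 0] == 0)


def test_elasticity_matches_finite_difference():
    """e_ij = dln(lambda)/dln(a_ij), checked by central differences."""
    A = tables.load_transition_matrix(1).entries
    E = od.elasticity_matrix(A)
    h = 1e-6
    for i in range(5):
        for j in range(5):
            if A[i, j] == 0:
                continue
            up, dn = A.copy(), A.copy()
            up[i, j] *= 1 + h
            dn[i, j] *= 1 - h
            fd = (np.log(od.dominant_eigenvalue(up))
                  - np.log(od.dominant_eigenvalue(dn))) / (np.log(up[i, j])
                                                          - np.log(dn[i, j]))
            assert abs(E[i, j] - fd) < 1e-4, (i, j)


def test_positive_elasticity_entries_raise_lambda():
    A = tables.load_transition_matrix(2).entries
    lam = od.dominant_eigenvalue(A)
    E = od.elasticity_matrix(A)
    i, j = np.unravel_index(np.argmax(E), E.shape)
    up = A.copy()
    up[i, j] *= 1.05
    assert od.dominant_eigenvalue(up) > lam


def test_reducible_or_degenerate_matrices_rejected():
    with pytest.raises(ValueError, match="zero"):
        od.dominant_eigenvalue(np.zeros((3, 3)))
    block = np.array([[0.5, 0.0], [0.0, 0.4]])  # two disconnected stages
    # the spectral radius is still defined, but the stable stage and
    # elasticities need a unique positive eigenvector
    assert od.dominant_eigenvalue(block) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="reducible"):
        od.stable_stage(block)
    with pytest.raises(ValueError, match="reducible"):
        od.elasticity_matrix(block)


def test_summarize_posterior_moments_and_bounds():
    st = od.summarize_posterior([3.0, 3.0, 3.0])
    assert (st.mean, st.sd, st.lo, st.hi) == (3.0, 0.0, 3.0, 3.0)
    st = od.summarize_posterior([1.0, 2.0, 3.0])
    assert st.mean == pytest.approx(2.0)
    assert st.sd == pytest.approx(1.0)  # sample standard deviation
    with pytest.raises(ValueError):
        od.summarize_posterior([])


def test_percentiles_match_sorted_index_oracle():
    rng = np.random.default_rng(12)
    x = rng.normal(size=10000)
    st = od.summarize_posterior(x)
    xs = np.sort(x)

    def brute(q):
        # linear interpolation between order statistics
        pos = q / 100 * (len(xs) - 1)
        lo = int(np.floor(pos))
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[min(lo + 1, len(xs) - 1)] * frac

    assert st.lo == pytest.approx(brute(2.5), abs=1e-12)
    assert st.hi == pytest.approx(brute(97.5), abs=1e-12)


def test_chi_square_structure_hand_computed():
    stat, p = od.chi_square_structure([50, 50], [0.5, 0.5])
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
    # 3-cell hand arithmetic: O=(30,50,20), proportions (0.25,0.5,0.25)
    obs = np.array([30.0, 50.0, 20.0])
    exp = np.array([25.0, 50.0, 25.0])
    stat, p = od.chi_square_structure(obs, [0.25, 0.5, 0.25])
    assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())
    # 5-stage stable distribution is collapsed to (S, J, adults)
    w = od.stable_stage(tables.load_transition_matrix(1).entries)
    stat, p = od.chi_square_structure([44, 72, 97], w)
    assert stat > 0 and 0 <= p <= 1
    with pytest.raises(ValueError, match="expected"):
        od.chi_square_structure([5, 5], [1.0, 0.0])


def test_observed_initial_structure_differs_from_stable_stage():
    """The field rosters are far from the model's stable distribution."""
    init = tables.load_initial_counts()
    for pop in tables.POPULATIONS:
        row = init[init["population"] == pop].iloc[0]
        w = od.stable_stage(tables.load_transition_matrix(pop).entries)
        stat, p = od.chi_square_structure(
            [row["seedlings"], row["juveniles"], row["adults"]], w
        )
        assert p < 1e-4
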