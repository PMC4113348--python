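"""Eigen-analysis of projection matrices and posterior summaries.

For a nonnegative irreducible projection matrix A the Perron-Frobenius
theorem gives a unique dominant eigenvalue lambda (the asymptotic growth
rate), a positive right eigenvector w (stable stage distribution) and a
positive left eigenvector v (reproductive values).  Elasticities follow
Caswell:  e_ij = (a_ij / lambda) * v_i w_j / <v, w>,  and sum to one.

Posterior summaries are computed per draw and then averaged: each MCMC
draw yields a matrix, its eigen-statistics are evaluated, and the mean,
standard deviation and 2.5/97.5 percentile bounds of those per-draw
statistics characterize the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .projection import ProjectionMatrix
from .stages import LIVE_STAGES

__all__ = [
    "dominant_eigenvalue",
    "stable_stage",
    "reproductive_value",
    "elasticity_matrix",
    "summarize_posterior",
    "chi_square_structure",
    "PosteriorStat",
    "DemographySummary",
]


def _as_array(A) -> np.ndarray:
    if isinstance(A, ProjectionMatrix):
        return A.entries
    return np.asarray(A, dtype=float)


def _check_matrix(A: np.ndarray, require_irreducible: bool = False) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(A < 0):
        raise ValueError("matrix must be nonnegative")
    if not A.any():
        raise ValueError("zero matrix has no dominant eigenvalue")
    if require_irreducible and _is_reducible(A):
        raise ValueError("matrix is reducible; dominant eigen-structure not unique")


def _is_reducible(A: np.ndarray) -> bool:
    n = A.shape[0]
    reach = (np.eye(n) + (A > 0)).astype(bool)
    # boolean closure by repeated squaring
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        reach = reach @ reach
    return not reach.all()


def _eig(A: np.ndarray):
    """Dominant eigenvalue with right and left eigenvectors (positive, v.w scaled)."""
    vals, vl, vr = linalg.eig(A, left=True, right=True)
    idx = int(np.argmax(vals.real))
    lam = float(vals[idx].real)
    w = vr[:, idx].real
    v = vl[:, idx].real
    w = np.abs(w) / np.abs(w).sum()
    v = np.abs(v)
    return lam, w, v


def dominant_eigenvalue(A) -> float:
    """Spectral radius (asymptotic growth rate) of a projection matrix."""
    A = _as_array(A)
    _check_matrix(A)
    return _eig(A)[0]


def stable_stage(A) -> np.ndarray:
    """Dominant right eigenvector, normalized to sum to one.

    Requires an irreducible matrix so the vector is unique and positive.
    """
    A = _as_array(A)
    _check_matrix(A, require_irreducible=True)
    return _eig(A)[1]


def reproductive_value(A) -> np.ndarray:
    """Dominant left eigenvector, scaled so <v, w> = 1."""
    A = _as_array(A)
    _check_matrix(A, require_irreducible=True)
    _, w, v = _eig(A)
    return v / (v @ w)


def elasticity_matrix(A) -> np.ndarray:
    """Caswell elasticities e_ij = (a_ij/lambda) v_i w_j / <v, w>."""
    A = _as_array(A)
    _check_matrix(A, require_irreducible=True)
    lam, w, v = _eig(A)
    return (A / lam) * np.outer(v, w) / (v @ w)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorStat:
    """Elementwise mean, sample sd and central 95% credible bounds."""

    mean: np.ndarray
    sd: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def summarize_posterior(draws) -> PosteriorStat:
    """Summarize a sequence of per-draw scalars, vectors or matrices."""
    arr = np.asarray(list(draws), dtype=float)
    if arr.shape[0] == 0:
        raise ValueError("cannot summarize an empty list of draws")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean, dtype=float)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    return PosteriorStat(mean=mean, sd=sd, lo=lo, hi=hi)


def chi_square_structure(observed, expected_proportions):
    """Pearson chi-square of observed stage counts against a stable stage.

    The comparison uses the 3-category resolution at which initial
    censuses are reported (seedlings, juveniles, all adults pooled), so a
    5-stage stable distribution is collapsed before testing; df = 2.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if props.shape[0] == 5 and obs.shape[0] == 3:
        props = np.array([props[0], props[1], props[2:].sum()])
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes disagree")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be nonnegative with positive total")
    props = props / props.sum()
    expected = props * obs.sum()
    if np.any((expected == 0) & (obs > 0)):
        raise ValueError("expected count of 0 with positive observed count")
    keep = expected > 0
    stat, p = stats.chisquare(obs[keep], expected[keep])
    return float(stat), float(p)


@dataclass
class DemographySummary:
    """Per-population posterior demography.

    All fields are dictionaries keyed by 0-based population index.
    ``lam`` summarizes the asymptotic growth rate, ``stable`` the
    stable stage distribution (5-vector), ``elasticity`` the 5x5
    elasticity matrix; ``chi_square`` maps to (statistic, p) against the
    observed initial structure where one was supplied.
    """

    lam: dict[int, PosteriorStat]
    stable: dict[int, PosteriorStat]
    elasticity: dict[int, PosteriorStat]
    chi_square: dict[int, tuple[float, float]]

    def lambda_table(self):
        import pandas as pd

        rows = [
            (k + 1, st.mean, st.sd, st.lo, st.hi)
            for k, st in sorted(self.lam.items())
        ]
        return pd.DataFrame(
            rows, columns=["population", "mean", "sd", "lo2.5", "hi97.5"]
        )

    def stable_table(self):
        import pandas as pd

        rows = []
        for k, st in sorted(self.stable.items()):
            for i, stage in enumerate(LIVE_STAGES):
                rows.append((k + 1, stage, st.mean[i], st.sd[i]))
        return pd.DataFrame(rows, columns=["population", "stage", "mean", "sd"])
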