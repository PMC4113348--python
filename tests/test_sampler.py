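"""Posterior sampler: targeting, determinism, pooling behaviour."""

import numpy as np
import pytest

import orchidemog as od
from orchidemog.census import TransitionCounts
from orchidemog.sampler import _Gibbs


def test_prior_only_run_recovers_uniform_means():
    """With no data every probability parameter keeps its Uniform(0,1) prior."""
    counts = TransitionCounts.empty(2, 4, stream_map=[0, 1])
    sample = od.sample_posterior(counts, n_keep=2000, n_burn=500, seed=3)
    names = ("r", "s", "g_y", "t_sj", "t_sn", "g_j", "t_jn", "t_js", "phi")
    for name in names:
        mean = np.atleast_1d(sample.posterior_mean(name)).ravel()
        assert np.all(mean > 0.42) and np.all(mean < 0.58), (name, mean)
    # pooled across the 19 scalar probability slots the MC error shrinks
    pooled = np.concatenate(
        [np.atleast_1d(sample.posterior_mean(n)).ravel() for n in names]
    )
    assert abs(pooled.mean() - 0.5) < 0.05


def test_same_seed_bit_identical(study_counts, tmp_path):
    s1 = od.sample_posterior(study_counts, n_keep=40, n_burn=40, seed=9)
    s2 = od.sample_posterior(study_counts, n_keep=40, n_burn=40, seed=9)
    for name in s1.draws:
        assert np.array_equal(s1.draws[name], s2.draws[name]), name
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    s1.to_jsonl(p1)
    s2.to_jsonl(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_jsonl_roundtrip(study_counts, tmp_path):
    s1 = od.sample_posterior(study_counts, n_keep=10, n_burn=10, seed=1)
    path = tmp_path / "post.jsonl"
    s1.to_jsonl(path)
    s2 = od.PosteriorSample.from_jsonl(path)
    assert len(s2) == 10
    for name in s1.draws:
        np.testing.assert_allclose(s1.draws[name], s2.draws[name])
    assert s2.get_draw(3).n_populations == study_counts.n_populations


def test_cached_density_matches_reference_likelihood(study_counts):
    g = _Gibbs(study_counts, seed=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g.run(3, 3)
    cached = (g.T1.sum() + g.gap_cache.sum() + g.Ys.sum() + g.Yj.sum()
              + g.R.sum())
    assert cached == pytest.approx(od.log_likelihood(g.params, study_counts),
                                   abs=1e-8)


def test_impossible_recruits_raise_at_initialization():
    counts = TransitionCounts.empty(1, 14)
    counts.recruits.append((0, 5, 3, 0.0))  # recruits with zero exposure
    with pytest.raises(ValueError, match="population 1"):
        od.sample_posterior(counts, n_keep=10, n_burn=0, seed=0)


def test_posterior_concentrates_with_data(study_counts, study_fit, true_params):
    """Strongly informed shared parameters land near their generating values."""
    for name, tol in (("g_y", 0.06), ("t_sj", 0.04), ("g_j", 0.06)):
        assert abs(float(study_fit.posterior_mean(name))
                   - getattr(true_params, name)) < tol


def test_borrowing_strength_for_unobserved_juvenile_deaths(study_counts):
    """A population with no observed juvenile deaths still gets a positive,
    plausibly-sized posterior juvenile mortality via the shared offset."""
    counts = TransitionCounts(
        study_counts.n_populations, study_counts.n_transition_months,
        study_counts.stream_map,
        adult1=study_counts.adult1.copy(),
        young_s=study_counts.young_s.copy(),
        young_j=study_counts.young_j.copy(),
        adult_gaps=dict(study_counts.adult_gaps),
        recruits=list(study_counts.recruits),
    )
    k = 5  # population 6, the smallest juvenile sample
    deaths = counts.young_j[k, 4]
    counts.young_j[k, 0] += deaths  # observed-data condition: zero deaths
    counts.young_j[k, 4] = 0
    sample = od.sample_posterior(counts, n_keep=600, n_burn=400, seed=21)
    from scipy.special import expit

    mort = 1.0 - expit(sample.draws["a"][:, k] + sample.draws["b"])
    post_mean = float(mort.mean())
    others = np.delete(np.arange(counts.n_populations), k)
    pooled = (counts.young_j[others, 4].sum()
              / counts.young_j[others].sum())
    assert 0.0 < post_mean < 3.0 * pooled
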