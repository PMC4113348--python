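"""Shared fixtures: one synthetic study and one posterior fit per session."""

from __future__ import annotations

import numpy as np
import pytest

import orchidemog as od


@pytest.fixture(scope="session")
def study_census():
    """Default seven-population synthetic census (fixed seed)."""
    return od.simulate_census(od.default_sim_config(seed=11))


@pytest.fixture(scope="session")
def study_counts(study_census):
    return od.tabulate(study_census)


@pytest.fixture(scope="session")
def study_fit(study_counts):
    """A moderate posterior fit reused across tests."""
    return od.sample_posterior(study_counts, n_keep=1200, n_burn=600, seed=11)


@pytest.fixture(scope="session")
def true_params():
    return od.default_true_params()


@pytest.fixture()
def tiny_census_df():
    """Three records: one individual going S -> S -> J."""
    import pandas as pd

    return pd.DataFrame(
        {
            "population": [1, 1, 1],
            "stream": [1, 1, 1],
            "month": [0, 1, 2],
            "individual": ["i1", "i1", "i1"],
            "stage": ["S", "S", "J"],
        }
    )


def single_pop_params(n_months: int, m: float = 0.02, r: float = 0.6,
                      s: float = 0.3, sigma: float = 1e-9) -> od.HierParams:
    """One-population parameter set with uniform adult rates (test helper)."""
    from scipy.special import logit

    return od.HierParams(
        stage_effect=np.full(3, logit(m)),
        pop_effect=np.zeros(1),
        month_effect=np.zeros((2, n_months - 1)),
        sigma_month=np.array([sigma, sigma]),
        r=np.full((1, 3), r),
        s=np.full((1, 3), s),
        a=np.array([1.5]),
        b=0.5,
        g_y=0.6, t_sj=0.9, t_sn=0.6, g_j=0.25, t_jn=0.5, t_js=0.8,
        f=np.array([0.005]),
        phi=0.11,
        stream_map=np.zeros(1, dtype=int),
    )
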