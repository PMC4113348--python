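"""Packaged study tables.

Ships the published summary tables for the seven *Lepanthes rupestris*
populations as CSV fixtures: initial stage counts, fruit and recruit
totals, the posterior-mean (and sd) 13-month transition matrices, the
posterior-mean (and sd) elasticity matrices, and the stable stage
distributions.  Matrices are stored with columns = from-stage and rows =
to-stage in the order (S, J, A0, A1, A2).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .projection import ProjectionMatrix
from .stages import LIVE_STAGES

__all__ = [
    "load_initial_counts",
    "load_fruits_recruits",
    "load_transition_matrix",
    "load_transition_sd",
    "load_elasticity_matrix",
    "load_stable_stage",
    "POPULATIONS",
]

POPULATIONS = tuple(range(1, 8))


def _read(name: str) -> pd.DataFrame:
    with resources.files("orchidemog.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_initial_counts() -> pd.DataFrame:
    """Initial roster per population: seedlings, juveniles, adults."""
    return _read("initial_counts.csv")


def load_fruits_recruits() -> pd.DataFrame:
    """Whole-survey fruit and recruit totals per population."""
    return _read("fruits_recruits.csv")


def _matrix_from(df: pd.DataFrame, population: int) -> np.ndarray:
    sub = df[df["population"] == population].set_index("to_stage")
    return sub.loc[list(LIVE_STAGES), list(LIVE_STAGES)].to_numpy(dtype=float)


def load_transition_matrix(population: int) -> ProjectionMatrix:
    """Published mean 13-month transition matrix as a ProjectionMatrix."""
    if population not in POPULATIONS:
        raise ValueError(f"population must be 1..7, got {population}")
    return ProjectionMatrix.from_array(
        _matrix_from(_read("transitions_mean.csv"), population),
        population=population - 1,
    )


def load_transition_sd(population: int) -> np.ndarray:
    return _matrix_from(_read("transitions_sd.csv"), population)


def load_elasticity_matrix(population: int) -> np.ndarray:
    """Published mean elasticity matrix (5x5 array)."""
    return _matrix_from(_read("elasticities_mean.csv"), population)


def load_stable_stage(population: int) -> pd.DataFrame:
    """Published stable stage distribution (mean and sd per stage)."""
    df = _read("stable_stage.csv")
    return df[df["population"] == population].set_index("stage").loc[list(LIVE_STAGES)]
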