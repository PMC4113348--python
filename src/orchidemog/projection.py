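"""Assembly of the 13-month Lefkovitch projection matrix.

Stage order is (S, J, A0, A1, A2); columns are the starting stage and
rows the stage one 13-month interval later.  The adult block is the
monthly transition kernel (monthly random effect at its central value 0)
raised to the 13th power; seedling and juvenile columns come straight
from the 13-month conditional fate chain.  Fecundity is added once, on
top of the assembled matrix, never inside the power step, so an adult
lineage cannot reproduce twice within one interval through the matrix.

Fecundity entries accumulate fruit-weighted occupancy: a stage-c adult
contributes ``E_c = sum_{t=0..12} P(A1 at t | c) + 7.8 * P(A2 at t | c)``
small-adult-equivalent months over the interval (survival-discounted),
and produces ``f[k]`` recruits per equivalent month, split ``phi`` to
seedlings and ``1 - phi`` to juveniles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import monthly_kernel, young_fate_probs
from .params import RHO, HierParams
from .stages import LIVE_STAGES, STAGE_INDEX

__all__ = [
    "ProjectionMatrix",
    "monthly_adult_kernel",
    "adult_13month",
    "fecundity_exposure",
    "assemble_lefkovitch",
]

LAG = 13


@dataclass
class ProjectionMatrix:
    """A 5x5 nonnegative 13-month projection matrix (columns = from-stage).

    ``fecundity`` holds the reproduction component separately so the
    survival/transition part can be checked for column-stochasticity;
    ``entries`` is the full matrix (survival + fecundity).
    """

    entries: np.ndarray
    fecundity: np.ndarray = field(default=None)  # type: ignore[assignment]
    population: int | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.fecundity is None:
            self.fecundity = np.zeros_like(self.entries)
        self.fecundity = np.asarray(self.fecundity, dtype=float)
        self.validate()

    @property
    def survival_part(self) -> np.ndarray:
        return self.entries - self.fecundity

    def validate(self, tol: float = 1e-9) -> None:
        if self.entries.shape != (5, 5):
            raise ValueError("projection matrix must be 5x5")
        if np.any(self.entries < -tol):
            raise ValueError("projection matrix has negative entries")
        if np.any(self.fecundity < -tol):
            raise ValueError("fecundity part has negative entries")
        colsums = self.survival_part.sum(axis=0)
        if np.any(colsums > 1.0 + 1e-6):
            raise ValueError(
                f"survival/transition column sums exceed 1: {colsums}"
            )
        # non-reproducing adults produce nothing and cannot regress
        i_s, i_j, i_a0 = STAGE_INDEX["S"], STAGE_INDEX["J"], STAGE_INDEX["A0"]
        if abs(self.entries[i_s, i_a0]) > tol or abs(self.entries[i_j, i_a0]) > tol:
            raise ValueError("A0 column must carry no mass to S or J")

    @classmethod
    def from_array(cls, entries, population: int | None = None) -> "ProjectionMatrix":
        """Wrap a printed/mean matrix, inferring the fecundity mask.

        For matrices not assembled from parameters the reproduction
        component is taken to be the S-row entries of the J, A1, A2
        columns and the J-row entries of the A1, A2 columns (adults and
        juveniles cannot regress, so any such mass is fecundity).
        """
        entries = np.asarray(entries, dtype=float)
        fec = np.zeros_like(entries)
        i_s, i_j = STAGE_INDEX["S"], STAGE_INDEX["J"]
        for col in ("J", "A1", "A2"):
            fec[i_s, STAGE_INDEX[col]] = entries[i_s, STAGE_INDEX[col]]
        for col in ("A1", "A2"):
            fec[i_j, STAGE_INDEX[col]] = entries[i_j, STAGE_INDEX[col]]
        return cls(entries=entries, fecundity=fec, population=population)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=LIVE_STAGES, columns=LIVE_STAGES)


def monthly_adult_kernel(params: HierParams, population: int) -> np.ndarray:
    """4x4 monthly adult kernel with the month effect at its mean (0)."""
    return monthly_kernel(params, population, month=None)


def adult_13month(kernel: np.ndarray, lag: int = LAG) -> np.ndarray:
    """Live 3x3 block of the kernel raised to the 13th power.

    The dead column is absorbing, so powering the live submatrix equals
    taking the live block of the powered full kernel; column-sum deficits
    are the 13-month mortalities.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape == (4, 4):
        live = kernel[:3, :3]
    elif kernel.shape == (3, 3):
        live = kernel
    else:
        raise ValueError("kernel must be 3x3 or 4x4")
    return np.linalg.matrix_power(live, lag)


def fecundity_exposure(params: HierParams, population: int,
                       lag: int = LAG) -> np.ndarray:
    """Expected A1-equivalent months over the interval per starting adult stage.

    Returns a 3-vector over (A0, A1, A2): survival-discounted occupancy
    of the reproductive stages, with A2 months weighted ``RHO``.
    """
    live = monthly_adult_kernel(params, population)[:3, :3]
    occ = np.eye(3)  # columns: starting stage
    weights = np.array([0.0, 1.0, RHO])
    total = weights @ occ
    for _ in range(lag - 1):
        occ = live @ occ
        total = total + weights @ occ
    return total


def assemble_lefkovitch(params: HierParams, population: int,
                        lag: int = LAG) -> ProjectionMatrix:
    """Build the full 5x5 13-month matrix for one population."""
    A = np.zeros((5, 5))
    # young columns: 13-month conditional chains (D mass is the deficit)
    A[[0, 1, 2, 3], 0] = young_fate_probs(params, "S", population)[:4]
    A[[1, 2, 3, 4], 1] = young_fate_probs(params, "J", population)[:4]
    # adult block
    A[2:, 2:] = adult_13month(monthly_adult_kernel(params, population), lag=lag)
    # fecundity, added once on the assembled interval matrix
    fec = np.zeros((5, 5))
    exposure = fecundity_exposure(params, population, lag=lag)
    recruits = params.f[population] * exposure  # per starting A0/A1/A2 adult
    fec[0, 3] = params.phi * recruits[1]
    fec[1, 3] = (1.0 - params.phi) * recruits[1]
    fec[0, 4] = params.phi * recruits[2]
    fec[1, 4] = (1.0 - params.phi) * recruits[2]
    # A0 column stays fecundity-free by construction (Fig. 1 topology:
    # new individuals come only from currently reproducing adults)
    return ProjectionMatrix(entries=A + fec, fecundity=fec, population=population)
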