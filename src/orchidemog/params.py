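"""Parameters of the hierarchical transition model.

The model decomposes each demographic rate into interpretable pieces:

* monthly adult mortality on the logit scale:
  ``logit m[k,j,i] = stage_effect[i] + month_effect[q(k), j] + pop_effect[k]``
  with ``q(k)`` the stream housing population ``k``; month effects are
  random deviates with stream-specific standard deviation ``sigma_month``;
* conditional adult transitions: given survival, an adult of stage ``i``
  in population ``k`` is reproductive next month with probability
  ``r[k, i]`` and, given reproductive, large with probability ``s[k, i]``;
* young survival on the logit scale: seedlings ``logit s_y[k] = a[k]``,
  juveniles ``logit s_j[k] = a[k] + b`` (one shared offset ``b``);
* young progression over a 13-month interval as a conditional chain
  shared across populations (``g_y``, ``t_sj``, ``t_sn`` for seedlings;
  ``g_j``, ``t_jn``, ``t_js`` for juveniles);
* recruitment: ``f[k]`` is the monthly recruit production rate per
  small-reproductive-adult equivalent, large reproductive adults produce
  ``RHO = 7.8`` times as much, and a share ``phi`` of recruits are
  seedlings (both shared across populations).

Identifiability: there is no global intercept (the three stage effects act
as per-stage intercepts) and ``pop_effect[0]`` is fixed at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = ["HierParams", "RHO"]

# Fruit production of a large reproductive adult relative to a small one.
# Fixed constant of the model, not an estimated parameter.
RHO: float = 7.8

_SCALARS_PROB = ("g_y", "t_sj", "t_sn", "g_j", "t_jn", "t_js", "phi")


@dataclass
class HierParams:
    """Every latent quantity of the hierarchical model.

    Array shapes (``K`` populations, ``M`` transition months):
    ``stage_effect`` (3,), ``pop_effect`` (K,), ``month_effect`` (2, M),
    ``sigma_month`` (2,), ``r`` and ``s`` (K, 3), ``a`` (K,), ``f`` (K,),
    ``stream_map`` (K,) with entries in {0, 1}.
    """

    stage_effect: np.ndarray
    pop_effect: np.ndarray
    month_effect: np.ndarray
    sigma_month: np.ndarray
    r: np.ndarray
    s: np.ndarray
    a: np.ndarray
    b: float
    g_y: float
    t_sj: float
    t_sn: float
    g_j: float
    t_jn: float
    t_js: float
    f: np.ndarray
    phi: float
    stream_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("stage_effect", "pop_effect", "month_effect", "sigma_month",
                     "r", "s", "a", "f"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.stream_map is None:
            # default: all populations in stream 0
            self.stream_map = np.zeros(self.n_populations, dtype=int)
        self.stream_map = np.asarray(self.stream_map, dtype=int)

    # -- basic dimensions -------------------------------------------------
    @property
    def n_populations(self) -> int:
        return self.pop_effect.shape[0]

    @property
    def n_transition_months(self) -> int:
        return self.month_effect.shape[1]

    @property
    def rho(self) -> float:
        return RHO

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        K = self.n_populations
        if self.stage_effect.shape != (3,):
            raise ValueError("stage_effect must have shape (3,)")
        if self.month_effect.ndim != 2 or self.month_effect.shape[0] != 2:
            raise ValueError("month_effect must have shape (2, M)")
        if self.sigma_month.shape != (2,):
            raise ValueError("sigma_month must have shape (2,)")
        for name in ("r", "s"):
            arr = getattr(self, name)
            if arr.shape != (K, 3):
                raise ValueError(f"{name} must have shape ({K}, 3)")
        for name in ("a", "f", "stream_map"):
            if getattr(self, name).shape != (K,):
                raise ValueError(f"{name} must have shape ({K},)")
        if self.pop_effect[0] != 0.0:
            raise ValueError("pop_effect[0] is the reference level and must be 0")
        if not np.all((self.stream_map == 0) | (self.stream_map == 1)):
            raise ValueError("stream_map entries must be 0 or 1")
        if np.any(self.sigma_month <= 0):
            raise ValueError("sigma_month must be positive")
        for name in _SCALARS_PROB:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("r", "s"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} has entries outside [0, 1]")
        if np.any(self.f < 0):
            raise ValueError("f must be nonnegative")

    def probability_fields(self) -> dict[str, np.ndarray | float]:
        """The probability-typed parameters (for coverage / prior checks)."""
        out: dict[str, np.ndarray | float] = {"r": self.r, "s": self.s}
        for name in _SCALARS_PROB:
            out[name] = getattr(self, name)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for fld in fields(self):
            v = getattr(self, fld.name)
            out[fld.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "HierParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "HierParams":
        return cls.from_dict(json.loads(text))

    def copy(self) -> "HierParams":
        return HierParams.from_dict(self.to_dict())
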