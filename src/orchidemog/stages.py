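"""Life-history stage codes for *Lepanthes rupestris*.

Five live stages plus an absorbing dead state:

``S``
    seedling — small plant, no petiole on any leaf.
``J``
    juvenile — at least one lepanthiform sheath, never flowered.
``A0``
    non-reproducing adult — has flowered before, currently not flowering.
``A1``
    small reproductive adult — exactly one active inflorescence.
``A2``
    large reproductive adult — two or more active inflorescences.
``D``
    dead (absorbing).
"""

from __future__ import annotations

# Canonical orderings used throughout the package.
LIVE_STAGES: tuple[str, ...] = ("S", "J", "A0", "A1", "A2")
ADULT_STAGES: tuple[str, ...] = ("A0", "A1", "A2")
ALL_STAGES: tuple[str, ...] = LIVE_STAGES + ("D",)

# Fates reachable in one month by a live adult.
ADULT_FATES: tuple[str, ...] = ("A0", "A1", "A2", "D")
# Fates reachable over a 13-month interval by seedlings and juveniles.
# Seedlings cannot reach A2 in 13 months; juveniles cannot regress to S.
SEEDLING_FATES: tuple[str, ...] = ("S", "J", "A0", "A1", "D")
JUVENILE_FATES: tuple[str, ...] = ("J", "A0", "A1", "A2", "D")

STAGE_INDEX = {code: i for i, code in enumerate(LIVE_STAGES)}
ADULT_INDEX = {code: i for i, code in enumerate(ADULT_STAGES)}


def is_adult(code: str) -> bool:
    return code in ADULT_INDEX


def is_young(code: str) -> bool:
    return code in ("S", "J")


def validate_stage(code: str) -> str:
    if code not in ALL_STAGES:
        raise ValueError(f"unknown stage code {code!r}; expected one of {ALL_STAGES}")
    return code
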