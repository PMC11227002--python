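"""Five-state health space: disease accumulation, disability, and death.

The state space distinguishes, at each survey wave, people with no chronic
disease, exactly one disease, multimorbidity (two or more diseases) without
ADL disability, multimorbidity with ADL disability, and death.  Transitions
are forward-only: chronic diseases are ever-diagnosed (irreversible) and
disability within multimorbidity is treated as non-reversing, so severity can
only stay constant or increase, and death is absorbing.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class State(IntEnum):
    """Health states ordered by severity rank (the enum value)."""

    NONE = 0   # no chronic disease
    ONE = 1    # exactly one chronic disease
    DFMM = 2   # disability-free multimorbidity (>=2 diseases, no ADL difficulty)
    DMM = 3    # disabling multimorbidity (>=2 diseases, >=1 ADL difficulty)
    DEAD = 4   # absorbing

    @property
    def severity_rank(self) -> int:
        return int(self)


LIVING_STATES: tuple[State, ...] = (State.NONE, State.ONE, State.DFMM, State.DMM)
N_STATES = 5

#: permitted transitions (origin -> destination); severity rank never decreases
ALLOWED_TRANSITIONS = np.zeros((N_STATES, N_STATES), dtype=bool)
for _o in State:
    for _d in State:
        if _o == State.DEAD:
            ALLOWED_TRANSITIONS[_o, _d] = _d == State.DEAD
        else:
            ALLOWED_TRANSITIONS[_o, _d] = _d.severity_rank >= _o.severity_rank


def permitted_destinations(origin: State) -> tuple[State, ...]:
    """Destinations reachable from ``origin`` (including staying put)."""
    return tuple(State(d) for d in np.flatnonzero(ALLOWED_TRANSITIONS[origin]))


#: the seven ever-diagnosed chronic-disease flags shared across the surveys
DISEASES: tuple[str, ...] = (
    "arthritis",
    "cancer",
    "diabetes",
    "heart_problems",
    "hypertension",
    "stroke",
    "respiratory_problems",
)

#: the four ADL-difficulty items common to all three surveys
ADLS: tuple[str, ...] = (
    "adl_eating",
    "adl_bathing",
    "adl_walking",
    "adl_bed_transfer",
)

SEXES: tuple[str, ...] = ("male", "female")
EDUCATION_LEVELS: tuple[str, ...] = ("primary_or_less", "secondary", "postsecondary")

#: short labels used in exported tables, indexed by State value
STATE_LABELS: tuple[str, ...] = ("none", "one", "dfmm", "dmm", "dead")


def snap_age(age, delta: int, anchor: int = 60):
    """Floor interview ages to the ``delta``-spaced grid anchored at ``anchor``."""
    age = np.asarray(age, dtype=float)
    snapped = anchor + delta * np.floor((age - anchor) / delta)
    return snapped if snapped.ndim else float(snapped)


def make_age_grid(delta: int, age_max: int = 100, start: int = 60) -> np.ndarray:
    """Grid of interval-start ages 60, 60+delta, ..., <= age_max."""
    if delta not in (2, 3):
        raise ValueError(f"wave interval must be 2 or 3 years, got {delta}")
    return np.arange(start, age_max + 1, delta, dtype=float)
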