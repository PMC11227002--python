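"""Multistate life-table engine: from transition matrices to expectancies.

Given row-stochastic transition matrices on the wave-spaced age grid, the
engine propagates state-occupancy probabilities from age 60 and converts them
into expected years in each living state.  Each interval of length delta is
credited to the state occupied at its start (the standard discrete-time
occupancy-sum construction); after the last grid age everyone transitions to
death, closing the finite grid.  Conditional expectancies (by starting state
at 60) are averaged with the observed initial distribution — the weighted
share of person-waves in each state over ages 60-69 — to give population
expectancies, the multimorbidity-free / multimorbid aggregates, and shares of
total life expectancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import TransitionProbabilityArray
from .states import LIVING_STATES, N_STATES, STATE_LABELS, State


class ExpectancyError(ValueError):
    pass


@dataclass
class InitialDistribution:
    """Baseline distribution over living states (ages 60-69 average).

    When estimated from a panel, ``pi_vcov`` carries the person-clustered
    sampling covariance of the shares so that downstream intervals can
    propagate baseline uncertainty; a distribution built from known shares
    leaves it ``None``.
    """

    pi: np.ndarray
    age_band: tuple[float, float] = (60.0, 69.0)
    stratum: dict = field(default_factory=dict)
    pi_vcov: np.ndarray | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,):
            raise ExpectancyError("pi must have one entry per living state")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ExpectancyError("pi must be nonnegative and sum to 1 within 1e-12")
        if self.pi_vcov is not None:
            self.pi_vcov = np.asarray(self.pi_vcov, dtype=float)
            if self.pi_vcov.shape != (4, 4):
                raise ExpectancyError("pi_vcov must be 4x4")


def estimate_initial_distribution(
    coded: pd.DataFrame,
    stratum: dict | None = None,
    age_band: tuple[float, float] = (60.0, 69.0),
) -> InitialDistribution:
    """Survey-weighted share of living person-waves per state over the band."""
    stratum = dict(stratum or {})
    sub = coded
    for key, val in stratum.items():
        sub = sub[sub[key] == val]
    lo, hi = age_band
    sub = sub[(sub["age"] >= lo) & (sub["age"] <= hi) & (sub["state"] != State.DEAD.value)]
    if len(sub) == 0:
        raise ExpectancyError(
            f"no living person-waves aged {lo}-{hi} in stratum {stratum or 'pooled'}"
        )
    w = sub.groupby("state")["weight"].sum()
    pi = np.array([w.get(int(s), 0.0) for s in LIVING_STATES], dtype=float)
    total = pi.sum()
    pi = pi / total
    # linearized covariance of the weighted shares, clustered by person:
    # pi_hat_k = sum_i w_i 1[s_i = k] / sum_i w_i, influence summed per person
    ind = np.zeros((len(sub), 4))
    ind[np.arange(len(sub)), sub["state"].to_numpy(dtype=int)] = 1.0
    infl = sub["weight"].to_numpy(dtype=float)[:, None] * (ind - pi) / total
    per_person = pd.DataFrame(infl).groupby(sub["person_id"].to_numpy()).sum().to_numpy()
    pi_vcov = per_person.T @ per_person
    return InitialDistribution(pi=pi, age_band=age_band, stratum=stratum, pi_vcov=pi_vcov)


def occupancy_profile(parr: TransitionProbabilityArray, s_start: State) -> np.ndarray:
    """State-occupancy probabilities at every grid age, starting at age 60.

    Row 0 is a point mass on ``s_start``; row i+1 = row i @ P(age_i).  Total
    mass (including death) is conserved at every age.
    """
    n_ages = len(parr.ages)
    occ = np.zeros((n_ages, N_STATES))
    occ[0, int(s_start)] = 1.0
    for i in range(n_ages - 1):
        occ[i + 1] = occ[i] @ parr.probs[i]
    return occ


def band_average_distribution(
    parr: TransitionProbabilityArray,
    pi0: np.ndarray,
    age_band: tuple[float, float] = (60.0, 69.0),
    retention: float = 1.0,
) -> InitialDistribution:
    """Model-implied average living-state distribution over an age band.

    Propagates an entry distribution ``pi0`` (over living states at the first
    grid age) through the matrices and averages the living-state shares over
    the band's grid ages, weighting each age by its survival mass times the
    cumulative probability of still being under observation
    (``retention`` per wave, i.e. one minus the attrition rate).  This is the
    population analogue of the survey-weighted 60-69 baseline estimator when
    entry occurs at the first grid age and attrition is independent of
    state, and serves as the estimand in parameter-recovery studies.
    """
    pi0 = np.asarray(pi0, dtype=float)
    occ = np.zeros(N_STATES)
    occ[:4] = pi0 / pi0.sum()
    lo, hi = age_band
    total = np.zeros(4)
    for i, a in enumerate(parr.ages):
        if lo <= a <= hi:
            total += retention**i * occ[:4]
        if i < len(parr.ages) - 1:
            occ = occ @ parr.probs[i]
    if total.sum() <= 0:
        raise ExpectancyError(f"no grid ages inside band {age_band}")
    return InitialDistribution(pi=total / total.sum(), age_band=age_band)


@dataclass
class ExpectancyTable:
    """State expectancies at age 60 with aggregates and shares of LE.

    ``conditional[s, k]`` is the expected years in living state k for someone
    in state s at 60; ``e`` is the pi-weighted average.  Aggregates:
    multimorbidity-free LE (none + one disease), multimorbid LE (MMLE:
    disability-free + disabling multimorbidity), and total LE.  Percent
    shares are computed from unrounded expectancies.
    """

    conditional: np.ndarray  # (4 starting states, 4 living states)
    pi: np.ndarray
    delta: int
    e: np.ndarray = field(init=False)
    mmfree_le: float = field(init=False)
    mmle: float = field(init=False)
    le: float = field(init=False)
    pct: np.ndarray = field(init=False)
    pct_mmfree: float = field(init=False)
    pct_mmle: float = field(init=False)
    degenerate: bool = field(init=False, default=False)
    stratum: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    convention: str = "beginning-of-interval occupancy; terminal death after last grid age"

    def __post_init__(self):
        self.conditional = np.asarray(self.conditional, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.conditional.shape != (4, 4):
            raise ExpectancyError("conditional expectancies must be 4x4")
        if (self.conditional < 0).any():
            raise ExpectancyError("expectancies must be nonnegative")
        self.e = self.pi @ self.conditional
        self._compute_aggregates()

    def _compute_aggregates(self):
        self.mmfree_le = float(self.e[State.NONE] + self.e[State.ONE])
        self.mmle = float(self.e[State.DFMM] + self.e[State.DMM])
        self.le = float(self.e.sum())
        if abs(self.le - (self.mmfree_le + self.mmle)) > 1e-9:
            raise ExpectancyError("LE must equal the sum of the four state expectancies")
        if self.le <= 0:
            self.degenerate = True
            self.pct = np.full(4, np.nan)
            self.pct_mmfree = np.nan
            self.pct_mmle = np.nan
        else:
            self.pct = 100.0 * self.e / self.le
            self.pct_mmfree = float(100.0 * self.mmfree_le / self.le)
            self.pct_mmle = float(100.0 * self.mmle / self.le)

    def conditional_le(self, s_start: State) -> float:
        return float(self.conditional[int(s_start)].sum())

    def quantity(self, name: str) -> float:
        """Named scalar used by the delta method and reports."""
        return extract_quantity(self, name)

    def to_frame(self) -> pd.DataFrame:
        """Table-layout export: state rows then aggregate rows, with shares."""
        rows = []
        for k in LIVING_STATES:
            rows.append((STATE_LABELS[k], self.e[k], self.pct[k]))
        rows.append(("mmfree_le", self.mmfree_le, self.pct_mmfree))
        rows.append(("mmle", self.mmle, self.pct_mmle))
        rows.append(("le", self.le, 100.0 if not self.degenerate else np.nan))
        df = pd.DataFrame(rows, columns=["quantity", "expectancy", "pct_of_le"])
        if self.ci:
            df["lower_95"] = [self.ci.get(q, (np.nan, np.nan))[0] for q in df["quantity"]]
            df["upper_95"] = [self.ci.get(q, (np.nan, np.nan))[1] for q in df["quantity"]]
        return df


QUANTITY_NAMES = (
    "none",
    "one",
    "dfmm",
    "dmm",
    "mmfree_le",
    "mmle",
    "le",
    "pct_mmfree",
    "pct_mmle",
)


def extract_quantity(table: ExpectancyTable, name: str) -> float:
    if name in ("none", "one", "dfmm", "dmm"):
        return float(table.e[STATE_LABELS.index(name)])
    if name == "mmfree_le":
        return table.mmfree_le
    if name == "mmle":
        return table.mmle
    if name == "le":
        return table.le
    if name == "pct_mmfree":
        return table.pct_mmfree
    if name == "pct_mmle":
        return table.pct_mmle
    raise KeyError(f"unknown quantity {name!r}; choose from {QUANTITY_NAMES}")


def compute_expectancies(
    parr: TransitionProbabilityArray, pi: InitialDistribution | np.ndarray
) -> ExpectancyTable:
    """Expectancy table from a probability array and an initial distribution.

    e[s, k] = delta * sum over grid ages of the occupancy probability of
    living state k, starting from s at 60.
    """
    if not isinstance(pi, InitialDistribution):
        pi = InitialDistribution(pi=np.asarray(pi, float))
    parr.validate()
    conditional = np.zeros((4, 4))
    for s in LIVING_STATES:
        occ = occupancy_profile(parr, s)
        conditional[int(s)] = parr.delta * occ[:, :4].sum(axis=0)
    return ExpectancyTable(
        conditional=conditional, pi=pi.pi, delta=parr.delta, stratum=dict(parr.stratum)
    )


def aggregate_measures(table: ExpectancyTable) -> ExpectancyTable:
    """Recompute aggregates and percent shares from the state expectancies."""
    table._compute_aggregates()
    return table


def aggregates_from_states(e: np.ndarray | list) -> dict:
    """Aggregates implied by four state expectancies (none, one, dfmm, dmm).

    Used for worked examples where published state rows are the input.
    """
    e = np.asarray(e, dtype=float)
    if e.shape != (4,):
        raise ExpectancyError("expected four state expectancies")
    mmfree = float(e[0] + e[1])
    mmle = float(e[2] + e[3])
    le = float(e.sum())
    out = {"mmfree_le": mmfree, "mmle": mmle, "le": le}
    if le > 0:
        out.update(
            pct=100.0 * e / le,
            pct_mmfree=100.0 * mmfree / le,
            pct_mmle=100.0 * mmle / le,
        )
    return out
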