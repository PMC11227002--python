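"""Code raw person-wave records into the five-state space.

The raw unit is one row per person per wave carrying seven ever-diagnosed
chronic-disease flags, four ADL-difficulty flags, vital status, demographics
and a sampling weight.  Coding enforces the substantive conventions of the
state space: diseases are chronic and irreversible (carry-forward), disability
reversals within multimorbidity are not modelled (monotone state recode), and
death is absorbing.  The output is a coded panel plus the adjacent-wave
transition pairs that feed the multinomial-logit stage, together with an
audit of every exclusion applied on the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .states import (
    ADLS,
    ALLOWED_TRANSITIONS,
    DISEASES,
    State,
    snap_age,
)

ID_COLUMNS = ("person_id", "wave", "age", "sex", "education", "weight", "alive")


class PanelFormatError(ValueError):
    """Raised when a panel violates the input contract."""


@dataclass
class CodingAudit:
    """Counts of recodes and exclusions applied during coding.

    Mirrors the role of a participant flow chart: every row or person that is
    altered or removed is tallied under the reason it was touched.
    """

    disease_overrides: int = 0
    state_recodes: int = 0
    rows_under_60: int = 0
    rows_missing_items: int = 0
    single_wave_persons: int = 0
    wave_gap_exclusions: int = 0
    age_gap_exclusions: int = 0
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def _require_sorted(panel: pd.DataFrame) -> None:
    if "person_id" not in panel.columns or "wave" not in panel.columns:
        raise PanelFormatError("panel must carry person_id and wave columns")
    waves = panel.groupby("person_id", sort=False)["wave"].diff()
    if (waves.dropna() <= 0).any():
        raise PanelFormatError(
            "waves must be strictly increasing within each person; sort the "
            "panel by (person_id, wave) first"
        )
    # groupby preserves order, but interleaved person blocks break the
    # one-person-at-a-time contract of the carry-forward pass
    ids = panel["person_id"].to_numpy()
    first_seen: dict = {}
    prev = object()
    for i, pid in enumerate(ids):
        if pid != prev:
            if pid in first_seen:
                raise PanelFormatError(
                    f"rows for person {pid!r} are not contiguous; panel must be "
                    "sorted by (person_id, wave)"
                )
            first_seen[pid] = i
            prev = pid


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the input contract of a raw long-format panel."""
    missing = [c for c in ID_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelFormatError(f"panel missing required columns: {missing}")
    missing = [c for c in (*DISEASES, *ADLS) if c not in panel.columns]
    if missing:
        raise PanelFormatError(f"panel missing disease/ADL columns: {missing}")
    _require_sorted(panel)
    if (panel["weight"].fillna(0) < 0).any():
        raise PanelFormatError("sampling weights must be nonnegative")
    ages = panel.groupby("person_id", sort=False)["age"].diff().dropna()
    if (ages < 0).any():
        raise PanelFormatError("ages must be nondecreasing within a person")


def carry_forward_diseases(
    panel: pd.DataFrame, audit: CodingAudit | None = None
) -> pd.DataFrame:
    """Enforce ever-diagnosed irreversibility of the chronic-disease flags.

    A "no" (or missing) answer after any earlier "yes" is overridden to "yes";
    the number of overridden cells is logged in the audit.  Idempotent.
    """
    _require_sorted(panel)
    out = panel.copy()
    grouped = out.groupby("person_id", sort=False)
    alive = out["alive"].astype(bool) if "alive" in out.columns else pd.Series(True, out.index)
    n_overrides = 0
    for col in DISEASES:
        vals = out[col].astype(float)
        cummax = grouped[col].cummax().astype(float)
        # cummax leaves missing cells missing; an earlier "yes" still covers them
        cummax = cummax.groupby(out["person_id"], sort=False).ffill()
        # death rows carry no items: only living rows are filled
        ever = (cummax == 1.0) & alive
        overridden = ever & (vals != 1.0)  # catches both 0 and NaN after a yes
        n_overrides += int(overridden.sum())
        out[col] = vals.where(~ever, 1.0)
    if audit is not None:
        audit.disease_overrides += n_overrides
    return out


def count_diseases(flags, variant: str = "full"):
    """Disease count from a flag row/frame; ``no_hypertension`` drops that flag."""
    if variant not in ("full", "no_hypertension"):
        raise ValueError(f"unknown variant {variant!r}")
    cols = [d for d in DISEASES if not (variant == "no_hypertension" and d == "hypertension")]
    if isinstance(flags, pd.DataFrame):
        return flags[cols].sum(axis=1)
    if isinstance(flags, (pd.Series, dict)):
        flags = pd.Series(flags)
        return int(flags[cols].sum())
    raise TypeError("flags must be a DataFrame, Series or mapping")


def classify_disability(adls) -> np.ndarray | bool:
    """Disabled iff the person reports difficulty with at least one ADL."""
    if isinstance(adls, pd.DataFrame):
        return adls[list(ADLS)].sum(axis=1).to_numpy() >= 1
    adls = pd.Series(adls)
    return bool(adls[list(ADLS)].sum() >= 1)


def assign_state_values(alive, n_diseases, disabled) -> np.ndarray:
    """Vectorized state assignment from (alive, disease count, disability).

    Disability only distinguishes states within multimorbidity; with fewer
    than two diseases it is recorded descriptively but does not alter the
    state code.
    """
    alive = np.asarray(alive, dtype=bool)
    n = np.asarray(n_diseases, dtype=float)
    dis = np.asarray(disabled, dtype=bool)
    out = np.full(alive.shape, State.DEAD.value, dtype=np.int64)
    out[alive & (n == 0)] = State.NONE
    out[alive & (n == 1)] = State.ONE
    out[alive & (n >= 2) & ~dis] = State.DFMM
    out[alive & (n >= 2) & dis] = State.DMM
    return out


def assign_state(record, variant: str = "full") -> State:
    """State of a single person-wave record (mapping or Series)."""
    rec = pd.Series(record)
    if not bool(rec["alive"]):
        return State.DEAD
    n = count_diseases(rec, variant)
    disabled = classify_disability(rec)
    return State(int(assign_state_values([True], [n], [disabled])[0]))


def enforce_monotone_states(
    panel: pd.DataFrame, audit: CodingAudit | None = None, state_col: str = "state"
) -> pd.DataFrame:
    """Recode each state to the running maximum severity within a person.

    Disability reversals and any residual backward moves are folded forward;
    a living row after a death row is a data error, not a recode.
    """
    _require_sorted(panel)
    out = panel.copy()
    grouped = out.groupby("person_id", sort=False)[state_col]
    dead_seen = grouped.cummax() == State.DEAD.value
    after_death = dead_seen & (out[state_col] != State.DEAD.value)
    # cummax marks the death row itself; shift within person to look backwards
    prev_dead = dead_seen.groupby(out["person_id"], sort=False).shift(1, fill_value=False)
    if (prev_dead & (out[state_col] != State.DEAD.value)).any():
        bad = out.loc[prev_dead & (out[state_col] != State.DEAD.value), "person_id"].unique()
        raise PanelFormatError(f"living state recorded after death for persons {list(bad)[:5]}")
    recoded = grouped.cummax()
    n_recodes = int((recoded != out[state_col]).sum())
    out[state_col] = recoded
    if audit is not None:
        audit.state_recodes += n_recodes
    _ = after_death  # death rows themselves are legitimate
    return out


def code_panel(
    panel: pd.DataFrame, variant: str = "full", audit: CodingAudit | None = None
) -> tuple[pd.DataFrame, CodingAudit]:
    """Full coding chain: eligibility, carry-forward, complete-case, states.

    Steps, in order: drop person-waves under age 60 (eligibility starts at the
    first wave aged 60+), carry diseases forward, drop living rows still
    missing any disease or ADL item (complete case), assign states, enforce
    monotone severity.  Death rows never carry disease/ADL items and are kept.
    """
    if audit is None:
        audit = CodingAudit()
    validate_panel(panel)
    out = panel.copy()

    under = out["age"] < 60
    audit.rows_under_60 += int(under.sum())
    out = out.loc[~under].copy()

    out = carry_forward_diseases(out, audit)

    alive = out["alive"].astype(bool)
    item_cols = [*DISEASES, *ADLS]
    incomplete = alive & out[item_cols].isna().any(axis=1)
    audit.rows_missing_items += int(incomplete.sum())
    out = out.loc[~incomplete].copy()

    n_dis = count_diseases(out[list(DISEASES)].fillna(0), variant)
    disabled = classify_disability(out[list(ADLS)].fillna(0))
    out["n_diseases"] = n_dis.to_numpy()
    out["disabled"] = disabled
    out["state"] = assign_state_values(out["alive"].astype(bool), n_dis, disabled)
    out = enforce_monotone_states(out, audit)
    return out, audit


def build_transition_pairs(
    coded: pd.DataFrame, delta: int, audit: CodingAudit | None = None
) -> tuple[pd.DataFrame, CodingAudit]:
    """Adjacent-wave (origin, destination) pairs on the ``delta``-year grid.

    A pair is kept when the wave indices are consecutive and the snapped ages
    are exactly ``delta`` years apart; anything else is excluded and counted.
    Persons contributing no pair at all (single-wave persons) are tallied.
    Origin ages are snapped down to the grid anchored at 60.
    """
    if delta not in (2, 3):
        raise ValueError(f"wave interval must be 2 or 3 years, got {delta}")
    if audit is None:
        audit = CodingAudit()
    _require_sorted(coded)
    if "state" not in coded.columns:
        raise PanelFormatError("panel must be coded (run code_panel) before pairing")

    df = coded.copy()
    df["age_grid"] = snap_age(df["age"].to_numpy(), delta)
    g = df.groupby("person_id", sort=False)
    nxt = g[["wave", "age_grid", "state"]].shift(-1)
    has_next = nxt["wave"].notna()
    wave_ok = nxt["wave"] - df["wave"] == 1
    age_ok = nxt["age_grid"] - df["age_grid"] == delta
    origin_living = df["state"] != State.DEAD.value

    cand = has_next & origin_living
    keep = cand & wave_ok & age_ok
    audit.wave_gap_exclusions += int((cand & ~wave_ok).sum())
    audit.age_gap_exclusions += int((cand & wave_ok & ~age_ok).sum())

    pairs = pd.DataFrame(
        {
            "person_id": df.loc[keep, "person_id"].to_numpy(),
            "origin_state": df.loc[keep, "state"].to_numpy(dtype=np.int64),
            "dest_state": nxt.loc[keep, "state"].to_numpy(dtype=np.int64),
            "age": df.loc[keep, "age_grid"].to_numpy(),
            "sex": df.loc[keep, "sex"].to_numpy(),
            "education": df.loc[keep, "education"].to_numpy(),
            "weight": df.loc[keep, "weight"].to_numpy(dtype=float),
        }
    )

    contributing = set(pairs["person_id"].unique())
    audit.single_wave_persons += int(
        sum(1 for pid in df["person_id"].unique() if pid not in contributing)
    )

    if pairs.empty:
        raise PanelFormatError(
            "no valid transition pairs: "
            f"wave-gap exclusions={audit.wave_gap_exclusions}, "
            f"age-gap exclusions={audit.age_gap_exclusions}, "
            f"single-wave persons={audit.single_wave_persons}"
        )

    bad = ~ALLOWED_TRANSITIONS[pairs["origin_state"], pairs["dest_state"]]
    if bad.any():  # cannot happen after monotone recode; guard the contract
        raise PanelFormatError("emitted pairs violate the permitted-transition topology")
    return pairs, audit


def read_panel(path) -> pd.DataFrame:
    """Read a long-format panel from CSV (empty cells are missing values)."""
    panel = pd.read_csv(path)
    validate_panel(panel)
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)
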