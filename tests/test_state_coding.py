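"""State coding: carry-forward, disability, state assignment, pair building."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mmle
from mmle.coding import CodingAudit, PanelFormatError
from mmle.states import ADLS, ALLOWED_TRANSITIONS, DISEASES, State

from conftest import make_panel


def person(pid, waves):
    """Rows for one male default person; waves = [(wave, age, dis, adl[, alive])]."""
    rows = []
    for entry in waves:
        w, age, dis, adl, *rest = entry
        alive = rest[0] if rest else 1
        rows.append((pid, w, age, "male", "secondary", 1.0, alive, dis, adl))
    return rows


class TestCarryForward:
    def test_yes_then_no_is_overridden(self):
        panel = make_panel(
            person(1, [(1, 60, (), ()), (2, 62, ("diabetes",), ()), (3, 64, (), ())])
        )
        audit = CodingAudit()
        out = mmle.carry_forward_diseases(panel, audit)
        assert list(out["diabetes"]) == [0.0, 1.0, 1.0]
        assert audit.disease_overrides == 1

    def test_all_false_and_already_monotone_are_unchanged(self):
        panel = make_panel(
            person(1, [(1, 60, (), ()), (2, 62, (), ())])
            + person(2, [(1, 60, ("cancer",), ()), (2, 62, ("cancer",), ())])
        )
        audit = CodingAudit()
        out = mmle.carry_forward_diseases(panel, audit)
        pd.testing.assert_frame_equal(out, panel)
        assert audit.disease_overrides == 0

    def test_missing_after_yes_becomes_yes(self):
        panel = make_panel(person(1, [(1, 60, ("stroke",), ()), (2, 62, (), ())]))
        panel.loc[1, "stroke"] = np.nan
        out = mmle.carry_forward_diseases(panel)
        assert out["stroke"].tolist() == [1.0, 1.0]

    def test_unsorted_waves_rejected(self):
        panel = make_panel(person(1, [(2, 62, (), ()), (1, 60, (), ())]))
        with pytest.raises(PanelFormatError, match="strictly increasing"):
            mmle.carry_forward_diseases(panel)

    def test_interleaved_persons_rejected(self):
        rows = person(1, [(1, 60, (), ())]) + person(2, [(1, 60, (), ())])
        rows += person(1, [(2, 62, (), ())])
        with pytest.raises(PanelFormatError, match="contiguous"):
            mmle.carry_forward_diseases(make_panel(rows))

    @given(
        st.lists(
            st.lists(st.booleans(), min_size=4, max_size=4), min_size=1, max_size=6
        )
    )
    def test_idempotent_and_monotone(self, flag_rows):
        waves = [
            (
                i + 1,
                60 + 2 * i,
                tuple(d for d, f in zip(DISEASES[:4], flags) if f),
                (),
                1,
            )
            for i, flags in enumerate(flag_rows)
        ]
        panel = make_panel(person(1, waves))
        once = mmle.carry_forward_diseases(panel)
        twice = mmle.carry_forward_diseases(once)
        pd.testing.assert_frame_equal(once, twice)
        for col in DISEASES:
            assert once[col].is_monotonic_increasing


class TestCountsAndDisability:
    @pytest.mark.parametrize(
        "present,variant,expected",
        [
            (("hypertension", "diabetes"), "full", 2),
            (("hypertension", "diabetes"), "no_hypertension", 1),
            ((), "full", 0),
            ((), "no_hypertension", 0),
            (DISEASES, "full", 7),
            (DISEASES, "no_hypertension", 6),
        ],
    )
    def test_count_diseases(self, present, variant, expected):
        flags = {d: float(d in present) for d in DISEASES}
        assert mmle.count_diseases(flags, variant) == expected

    @pytest.mark.parametrize(
        "difficulties,expected",
        [((), False), (("adl_bathing",), True), (ADLS, True)],
    )
    def test_classify_disability(self, difficulties, expected):
        flags = {a: float(a in difficulties) for a in ADLS}
        assert mmle.classify_disability(flags) is expected


class TestAssignState:
    def truth(self, alive, n, disabled):
        if not alive:
            return State.DEAD
        if n == 0:
            return State.NONE
        if n == 1:
            return State.ONE
        return State.DMM if disabled else State.DFMM

    def test_exhaustive_truth_table(self):
        """assign_state is a pure function of (alive, count, disability)."""
        from mmle.coding import assign_state_values

        for alive, n, dis in itertools.product([True, False], range(8), [True, False]):
            got = State(int(assign_state_values([alive], [n], [dis])[0]))
            assert got == self.truth(alive, n, dis)

    def test_disability_without_multimorbidity_does_not_change_state(self):
        rec = {d: 0.0 for d in DISEASES} | {a: 0.0 for a in ADLS} | {"alive": 1}
        rec["adl_walking"] = 1.0
        assert mmle.assign_state(rec) == State.NONE
        rec["arthritis"] = 1.0
        assert mmle.assign_state(rec) == State.ONE

    def test_multimorbid_with_and_without_disability(self):
        rec = {d: 0.0 for d in DISEASES} | {a: 0.0 for a in ADLS} | {"alive": 1}
        rec["arthritis"] = rec["cancer"] = 1.0
        assert mmle.assign_state(rec) == State.DFMM
        rec["diabetes"] = 1.0
        rec["adl_eating"] = rec["adl_bathing"] = 1.0
        assert mmle.assign_state(rec) == State.DMM


class TestMonotoneStates:
    def frame(self, states):
        return pd.DataFrame(
            {
                "person_id": 1,
                "wave": range(1, len(states) + 1),
                "state": [int(s) for s in states],
            }
        )

    def test_disability_reversal_recoded(self):
        out = mmle.enforce_monotone_states(
            self.frame([State.DFMM, State.DMM, State.DFMM])
        )
        assert out["state"].tolist() == [2, 3, 3]

    def test_monotone_input_unchanged_and_idempotent(self):
        audit = CodingAudit()
        f = self.frame([State.NONE, State.ONE, State.DFMM])
        out = mmle.enforce_monotone_states(f, audit)
        assert out["state"].tolist() == [0, 1, 2]
        assert audit.state_recodes == 0
        out2 = mmle.enforce_monotone_states(out)
        pd.testing.assert_frame_equal(out, out2)

    def test_death_persists_and_resurrection_rejected(self):
        out = mmle.enforce_monotone_states(self.frame([State.DMM, State.DEAD]))
        assert out["state"].tolist() == [3, 4]
        with pytest.raises(PanelFormatError, match="after death"):
            mmle.enforce_monotone_states(self.frame([State.DEAD, State.ONE]))


class TestTransitionPairs:
    def test_three_waves_give_two_pairs(self):
        panel = make_panel(
            person(1, [(1, 60, (), ()), (2, 62, (), ()), (3, 64, ("cancer",), ())])
        )
        coded, audit = mmle.code_panel(panel)
        pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
        assert len(pairs) == 2
        assert pairs["dest_state"].tolist() == [0, 1]

    def test_wave_gap_excluded(self):
        rows = person(1, [(1, 60, (), ()), (3, 64, (), ())])
        rows += person(2, [(1, 60, (), ()), (2, 62, (), ())])
        coded, audit = mmle.code_panel(make_panel(rows))
        pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
        assert len(pairs) == 1
        assert audit.wave_gap_exclusions == 1

    def test_age_gap_excluded_but_later_adjacent_pairs_kept(self):
        rows = person(
            1, [(1, 60, (), ()), (2, 65, (), ()), (3, 67, (), ())]
        )  # 60->65 snaps to 60->64: not one interval apart
        coded, audit = mmle.code_panel(make_panel(rows))
        pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
        assert audit.age_gap_exclusions == 1
        assert len(pairs) == 1 and pairs["age"].iloc[0] == 64.0

    def test_death_between_waves_yields_dead_destination(self):
        rows = person(1, [(1, 70, ("cancer",), ())]) + [
            (1, 2, 72, "male", "secondary", 1.0, 0, None, None)
        ]
        coded, audit = mmle.code_panel(make_panel(rows))
        pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
        assert len(pairs) == 1
        assert pairs["dest_state"].iloc[0] == int(State.DEAD)
        assert pairs["origin_state"].iloc[0] == int(State.ONE)

    def test_under_60_and_missing_items_and_single_wave_audited(self):
        rows = person(1, [(1, 58, (), ()), (2, 60, (), ()), (3, 62, (), ())])
        rows += person(2, [(1, 60, (), ())])  # single wave
        rows += person(3, [(1, 60, None, ()), (2, 62, (), ())])  # missing diseases
        coded, audit = mmle.code_panel(make_panel(rows))
        pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
        assert audit.rows_under_60 == 1
        assert audit.rows_missing_items == 1
        assert audit.single_wave_persons == 2  # persons 2 and 3
        assert pairs["person_id"].unique().tolist() == [1]

    def test_empty_pairs_raise_with_diagnostics(self):
        panel = make_panel(person(1, [(1, 60, (), ())]))
        coded, audit = mmle.code_panel(panel)
        with pytest.raises(PanelFormatError, match="single-wave"):
            mmle.build_transition_pairs(coded, 2, audit)


class TestPanelProperties:
    def test_emitted_pairs_respect_topology(self, fitted_stratum):
        pairs = fitted_stratum["pairs"]
        assert ALLOWED_TRANSITIONS[pairs["origin_state"], pairs["dest_state"]].all()

    def test_no_hypertension_never_increases_multimorbidity(self, fitted_stratum):
        panel = fitted_stratum["panel"]
        full, _ = mmle.code_panel(panel, variant="full")
        nohyp, _ = mmle.code_panel(panel, variant="no_hypertension")
        mm_full = full.groupby("wave")["state"].apply(lambda s: (s >= 2).sum() - (s == 4).sum())
        mm_nohyp = nohyp.groupby("wave")["state"].apply(lambda s: (s >= 2).sum() - (s == 4).sum())
        assert (mm_nohyp <= mm_full).all()

    def test_coding_chain_idempotent_on_coded_panel(self, fitted_stratum):
        coded = fitted_stratum["coded"]
        again = mmle.carry_forward_diseases(coded)
        pd.testing.assert_frame_equal(again, coded)
        again2 = mmle.enforce_monotone_states(coded)
        pd.testing.assert_frame_equal(again2, coded)
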