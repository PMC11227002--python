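"""Synthetic generator: trajectories, panels, and the microsimulation oracle."""

import numpy as np
import pytest

import mmle
from mmle.states import State
from mmle.synthetic import GroundTruthScenario

from conftest import constant_hazard_array

ST = ("male", "primary_or_less")


def toy_scenario(betas, n_persons=50, seed=0, attrition=0.0, age_max=70):
    return GroundTruthScenario(
        betas={ST: betas},
        initial_distribution={ST: np.array([1.0, 0.0, 0.0, 0.0])},
        stratum_shares={ST: 1.0},
        entry_age_probs={60.0: 1.0},
        delta=2,
        age_max=age_max,
        attrition=attrition,
        n_persons=n_persons,
        seed=seed,
    )


class TestTrajectories:
    def test_no_progression_no_death_path_is_constant(self):
        sc = toy_scenario({s: {} for s in mmle.LIVING_STATES})
        states, ages = mmle.simulate_trajectory(sc, ST, 60.0, person_seed=5)
        assert all(s == State.NONE for s in states[:-1])
        assert states[-1] == State.DEAD  # forced terminal closure only
        assert ages[-1] == sc.age_max + sc.delta

    def test_certain_death_gives_two_state_paths(self):
        betas = {s: {State.DEAD: (500.0, 0.0)} for s in mmle.LIVING_STATES}
        sc = toy_scenario(betas)
        for seed in range(5):
            states, _ = mmle.simulate_trajectory(sc, ST, 60.0, person_seed=seed)
            assert len(states) == 2 and states[-1] == State.DEAD

    def test_fixed_seed_reproduces_path(self):
        sc = mmle.single_stratum_scenario(seed=3)
        a = mmle.simulate_trajectory(sc, ST, 60.0, person_seed=42)
        b = mmle.simulate_trajectory(sc, ST, 60.0, person_seed=42)
        assert a == b

    def test_severity_never_decreases(self):
        sc = mmle.single_stratum_scenario(seed=3)
        for seed in range(10):
            states, _ = mmle.simulate_trajectory(sc, ST, 64.0, person_seed=seed)
            ranks = [s.severity_rank for s in states]
            assert ranks == sorted(ranks)


class TestEmitPanel:
    def test_roundtrip_reproduces_latent_states(self, fitted_stratum):
        coded = fitted_stratum["coded"]
        assert (coded["state"] == coded["latent_state"]).all()

    def test_no_attrition_no_death_everyone_observed_to_ceiling(self):
        sc = toy_scenario({s: {} for s in mmle.LIVING_STATES}, n_persons=30)
        panel = mmle.emit_panel(sc)
        waves_per_person = panel.groupby("person_id").size()
        # ages 60..70 step 2 -> six observed waves each, none dead
        assert (waves_per_person == 6).all()
        assert panel["alive"].all()

    def test_retention_close_to_binomial(self):
        sc = toy_scenario({s: {} for s in mmle.LIVING_STATES}, n_persons=10_000,
                          attrition=0.1, seed=9)
        panel = mmle.emit_panel(sc)
        n0 = (panel["wave"] == 0).sum()
        n1 = (panel["wave"] == 1).sum()
        p = 0.9
        se = np.sqrt(p * (1 - p) / n0)
        assert abs(n1 / n0 - p) < 3 * se

    def test_panel_is_reproducible(self):
        sc1 = mmle.single_stratum_scenario(n_persons=300, seed=21)
        sc2 = mmle.single_stratum_scenario(n_persons=300, seed=21)
        assert mmle.emit_panel(sc1).equals(mmle.emit_panel(sc2))

    def test_scenario_validation(self):
        with pytest.raises(ValueError, match="attrition"):
            mmle.single_stratum_scenario(attrition=1.5)
        with pytest.raises(ValueError, match="n_persons"):
            mmle.single_stratum_scenario(n_persons=0)


class TestEmpiricalMatrix:
    def test_rows_match_truth_within_three_se(self):
        sc = mmle.single_stratum_scenario(n_persons=50_000, seed=13)
        panel = mmle.emit_panel(sc)
        coded, audit = mmle.code_panel(panel)
        pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
        truth = sc.true_probability_array(ST)
        age = 62.0
        rows, missing = mmle.empirical_transition_matrix(pairs, age=age)
        assert not missing
        cell_sizes = pairs[np.isclose(pairs["age"], age)].groupby("origin_state").size()
        for origin, row in rows.items():
            n = cell_sizes[int(origin)]
            t = truth.at(age)[int(origin)]
            se = np.sqrt(np.maximum(t * (1 - t), 1e-12) / n)
            assert np.all(np.abs(row - t) <= 3 * se + 1e-12)
            assert row.sum() == pytest.approx(1.0)

    def test_single_pair_is_point_mass_and_forbidden_cells_zero(self, fitted_stratum):
        pairs = fitted_stratum["pairs"].iloc[:1]
        rows, missing = mmle.empirical_transition_matrix(pairs)
        (origin,) = rows
        dest = pairs["dest_state"].iloc[0]
        assert rows[origin][dest] == 1.0
        full_rows, _ = mmle.empirical_transition_matrix(fitted_stratum["pairs"])
        for origin, row in full_rows.items():
            forbidden = ~mmle.ALLOWED_TRANSITIONS[int(origin)]
            assert np.all(row[forbidden] == 0.0)

    def test_empty_cell_flagged_missing(self, fitted_stratum):
        rows, missing = mmle.empirical_transition_matrix(
            fitted_stratum["pairs"], stratum={"sex": "female"}
        )
        assert set(missing) == set(mmle.LIVING_STATES)


class TestMicrosim:
    def test_geometric_closed_form_within_three_se(self):
        q, delta = 0.2, 2
        arr = constant_hazard_array(q, delta=delta)
        n_terms = len(arr.ages)
        closed = delta * (1 - (1 - q) ** n_terms) / q
        ms = mmle.microsim_expectancies(arr, [1, 0, 0, 0], n_reps=100_000, seed=1)
        assert abs(ms.le - closed) <= 3 * ms.le_se

    def test_certain_death_at_sixty_still_credits_first_interval(self):
        arr = constant_hazard_array(1.0)
        ms = mmle.microsim_expectancies(arr, [1, 0, 0, 0], n_reps=500, seed=1)
        assert ms.le == pytest.approx(arr.delta)
        assert ms.e[0] == pytest.approx(arr.delta)
        assert ms.le_se == 0.0

    def test_immortal_until_ceiling_gives_exact_total(self):
        arr = constant_hazard_array(0.0, delta=2, age_max=100)
        ms = mmle.microsim_expectancies(arr, [1, 0, 0, 0], n_reps=500, seed=1)
        # every lifetime occupies all grid ages: 100 - 60 + delta years
        assert ms.le == pytest.approx(100 - 60 + 2)
        assert ms.le_se == 0.0

    def test_oracle_agrees_with_engine(self, fitted_stratum):
        """Central correctness property: matrices vs microsimulation."""
        sc = fitted_stratum["scenario"]
        parr = sc.true_probability_array(ST)
        pi = sc.initial_distribution[ST]
        table = mmle.compute_expectancies(parr, pi)
        ms = mmle.microsim_expectancies(parr, pi, n_reps=100_000, seed=17)
        for q in ("none", "one", "dfmm", "dmm", "mmfree_le", "mmle", "le"):
            est, se = ms.quantity(q)
            assert abs(table.quantity(q) - est) <= 3 * se, q


class TestScenarioConfig:
    def test_yaml_roundtrip_preserves_the_process(self, tmp_path):
        import yaml

        from mmle.synthetic import scenario_from_config, scenario_to_config

        sc = mmle.default_scenario(n_persons=200, seed=5)
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(scenario_to_config(sc)))
        back = scenario_from_config(yaml.safe_load(path.read_text()))
        assert back.strata == sc.strata
        for st in sc.strata:
            a = sc.true_probability_array(st)
            b = back.true_probability_array(st)
            assert np.allclose(a.probs, b.probs, atol=1e-12)
        assert mmle.emit_panel(back).equals(mmle.emit_panel(sc))
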