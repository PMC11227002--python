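"""Weighted multinomial logit and transition-probability arrays."""

import warnings

import numpy as np
import pandas as pd
import pytest

import mmle
from mmle.estimation import EstimationError
from mmle.states import State

ST = ("male", "primary_or_less")


def pairs_frame(origins, dests, ages, weights=None):
    n = len(origins)
    return pd.DataFrame(
        {
            "origin_state": origins,
            "dest_state": dests,
            "age": ages,
            "sex": ["male"] * n,
            "education": ["primary_or_less"] * n,
            "weight": weights if weights is not None else np.ones(n),
        }
    )


class TestFitOriginModel:
    def test_recovers_truth_within_three_se(self):
        """Coefficients from a 50k-person panel sit within 3 SE of the truth."""
        sc = mmle.single_stratum_scenario(n_persons=50_000, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel = mmle.emit_panel(sc)
            coded, audit = mmle.code_panel(panel)
            pairs, audit = mmle.build_transition_pairs(coded, 2, audit)
            models = mmle.fit_models(pairs, 2)
        for origin, model in models.items():
            truth = np.array([sc.betas[ST][origin][d] for d in model.destinations])
            se = np.sqrt(np.diag(model.vcov)).reshape(model.coef.shape)
            assert np.all(np.abs(model.coef - truth) <= 3 * se), origin

    def test_all_stayers_give_degenerate_model(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pf = pairs_frame([0] * 20, [0] * 20, np.linspace(60, 80, 20))
            model = mmle.fit_origin_model(pf, State.NONE, delta=2)
        for age in (60.0, 80.0, 100.0):
            row = model.predict_row(age)
            assert row[State.NONE] == 1.0 and row.sum() == 1.0

    def test_saturated_binomial_matches_weighted_frequencies(self):
        # single age value: fitted probability equals the weighted share 2/6
        pf = pairs_frame([0, 0, 0], [0, 0, 1], [64.0, 64.0, 64.0], weights=[1.0, 3.0, 2.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = mmle.fit_origin_model(pf, State.NONE, delta=2, min_pairs=1)
        assert not model.has_age_term
        row = model.predict_row(64.0)
        assert row[State.ONE] == pytest.approx(2.0 / 6.0, abs=1e-8)
        assert row[State.NONE] == pytest.approx(4.0 / 6.0, abs=1e-8)

    def test_likelihood_ascent(self, fitted_stratum):
        for model in fitted_stratum["models"].values():
            assert model.loglik >= model.loglik_null

    def test_matches_statsmodels_on_unweighted_data(self, fitted_stratum):
        """Independent cross-check of the multinomial-logit maximizer."""
        sm = pytest.importorskip("statsmodels.api")
        pairs = fitted_stratum["pairs"]
        sub = pairs[pairs["origin_state"] == 1].copy()
        sub["weight"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = mmle.fit_origin_model(sub, State.ONE, delta=2)
        y = np.zeros(len(sub), dtype=int)
        for j, d in enumerate(model.destinations):
            y[sub["dest_state"] == int(d)] = j + 1
        X = np.column_stack([np.ones(len(sub)), sub["age"] - 60.0])
        ref = sm.MNLogit(y, X).fit(disp=False, maxiter=200, method="newton")
        assert np.allclose(model.coef, ref.params.T, atol=1e-6)

    def test_never_observed_destination_warns_and_stays_zero(self):
        rng = np.random.default_rng(0)
        ages = rng.choice([60.0, 62.0, 64.0], size=200)
        dests = rng.choice([1, 4], size=200, p=[0.7, 0.3])  # DFMM/DMM never seen
        pf = pairs_frame([1] * 200, dests, ages)
        with pytest.warns(UserWarning, match="never observed"):
            model = mmle.fit_origin_model(pf, State.ONE, delta=2)
        assert State.DFMM not in model.destinations
        assert model.predict_row(60.0)[State.DFMM] == 0.0

    def test_separation_raises(self):
        # destination perfectly determined by age: coefficients diverge
        ages = np.array([60.0] * 30 + [80.0] * 30)
        dests = np.array([0] * 30 + [4] * 30)
        pf = pairs_frame([0] * 60, dests, ages)
        with pytest.raises(EstimationError, match="separation|converge"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mmle.fit_origin_model(pf, State.NONE, delta=2)


class TestPredictAndBuild:
    def test_zero_coefficients_give_uniform_over_permitted(self):
        grid = mmle.make_age_grid(2)
        model = mmle.TransitionModel(
            origin=State.NONE,
            destinations=(State.ONE, State.DFMM, State.DMM, State.DEAD),
            coef=np.zeros((4, 2)),
            vcov=np.zeros((8, 8)),
            delta=2,
            age_grid=grid,
        )
        row = model.predict_row(70.0)
        assert np.allclose(row, 0.2)

    def test_intercept_only_model_is_age_constant(self):
        grid = mmle.make_age_grid(2)
        model = mmle.TransitionModel(
            origin=State.DMM,
            destinations=(State.DEAD,),
            coef=np.array([[0.3]]),
            vcov=np.zeros((1, 1)),
            delta=2,
            age_grid=grid,
            has_age_term=False,
        )
        rows = np.stack([model.predict_row(a) for a in grid])
        assert np.allclose(rows, rows[0])

    def test_hand_computed_softmax(self):
        # single destination, intercept 1.0, slope 0: p = e / (1 + e)
        grid = mmle.make_age_grid(2)
        model = mmle.TransitionModel(
            origin=State.DMM,
            destinations=(State.DEAD,),
            coef=np.array([[1.0, 0.0]]),
            vcov=np.zeros((2, 2)),
            delta=2,
            age_grid=grid,
        )
        row = model.predict_row(60.0)
        assert row[State.DEAD] == pytest.approx(0.731058578630005, abs=1e-12)
        assert row[State.DMM] == pytest.approx(0.268941421369995, abs=1e-12)

    def test_array_matches_scenario_truth_exactly(self):
        sc = mmle.single_stratum_scenario(seed=0)
        arr = sc.true_probability_array(ST)
        a = 72.0
        direct = mmle.matrix_from_coeffs(sc.betas[ST], a)
        assert np.allclose(arr.at(a), direct, atol=1e-12)

    def test_structural_zeros_and_row_sums(self, fitted_stratum):
        arr = fitted_stratum["parr"]
        arr.validate()
        forbidden = ~mmle.ALLOWED_TRANSITIONS
        assert np.all(arr.probs[:, forbidden] == 0.0)
        assert np.allclose(arr.probs.sum(axis=2), 1.0, atol=1e-12)

    def test_off_grid_age_rejected(self, fitted_stratum):
        with pytest.raises(EstimationError, match="grid"):
            mmle.predict_matrix(fitted_stratum["models"], 61.0)

    def test_forbidden_coefficients_rejected(self):
        with pytest.raises(ValueError, match="forbidden"):
            mmle.matrix_from_coeffs({State.DMM: {State.NONE: (0.0, 0.0)}}, 60.0)


class TestSerialization:
    def test_model_dict_roundtrip(self, fitted_stratum):
        import json

        for model in fitted_stratum["models"].values():
            payload = json.loads(json.dumps(model.to_dict()))
            back = mmle.TransitionModel.from_dict(payload)
            assert back.destinations == model.destinations
            assert np.allclose(back.coef, model.coef)
            assert np.allclose(back.vcov, model.vcov)
            for age in (60.0, 80.0, 100.0):
                assert np.allclose(back.predict_row(age), model.predict_row(age))
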