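import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mmle
from mmle.states import ADLS, DISEASES

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_panel(rows):
    """Long panel from compact row tuples.

    Each row: (person_id, wave, age, sex, education, weight, alive,
    diseases-present, adls-with-difficulty); diseases/adls are iterables of
    column names, or None for a missing block (e.g. death rows).
    """
    records = []
    for pid, wave, age, sex, edu, w, alive, dis, adl in rows:
        rec = {
            "person_id": pid,
            "wave": wave,
            "age": age,
            "sex": sex,
            "education": edu,
            "weight": w,
            "alive": alive,
        }
        for col in DISEASES:
            rec[col] = np.nan if dis is None else float(col in dis)
        for col in ADLS:
            rec[col] = np.nan if adl is None else float(col in adl)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def fitted_stratum():
    """One moderately sized single-stratum fit shared across test modules."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scenario = mmle.single_stratum_scenario(n_persons=8000, seed=11)
        panel = mmle.emit_panel(scenario)
        coded, audit = mmle.code_panel(panel)
        pairs, audit = mmle.build_transition_pairs(coded, scenario.delta, audit)
        models = mmle.fit_models(pairs, scenario.delta)
        parr = mmle.build_probability_array(models)
        pi = mmle.estimate_initial_distribution(coded)
    return {
        "scenario": scenario,
        "panel": panel,
        "coded": coded,
        "pairs": pairs,
        "audit": audit,
        "models": models,
        "parr": parr,
        "pi": pi,
        "table": mmle.compute_expectancies(parr, pi),
    }


@pytest.fixture()
def toy_probability_array():
    """Three-age array with hand-checkable entries (none/one/dead active)."""
    ages = np.array([60.0, 62.0, 64.0])
    P = np.zeros((3, 5, 5))
    for i in range(3):
        P[i, 2, 2] = 1.0
        P[i, 3, 3] = 1.0
        P[i, 4, 4] = 1.0
    P[0, 0] = [0.7, 0.2, 0.0, 0.0, 0.1]
    P[0, 1] = [0.0, 0.8, 0.0, 0.0, 0.2]
    P[1, 0] = [0.6, 0.3, 0.0, 0.0, 0.1]
    P[1, 1] = [0.0, 0.5, 0.0, 0.0, 0.5]
    P[2, 0] = [0.5, 0.3, 0.0, 0.0, 0.2]
    P[2, 1] = [0.0, 0.4, 0.0, 0.0, 0.6]
    arr = mmle.TransitionProbabilityArray(ages=ages, probs=P, delta=2)
    arr.validate()
    return arr


from mmle.validation import constant_hazard_array  # noqa: E402,F401  (shared fixture helper)
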