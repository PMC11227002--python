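#!/usr/bin/env python
"""Fit sex-stratified multinomial-logit transition models.

One weighted multinomial logit per living origin state and sex, linear in
age, reference = staying put.  Expands the fits onto the 60-100 grid as
row-stochastic matrices and writes the tidy (age, origin, destination,
probability) table that a transition-probability figure would plot.
"""

import warnings
from pathlib import Path

import pandas as pd

import mmle

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main():
    pairs_path = SCRATCH / "pairs.csv"
    if not pairs_path.exists():
        raise SystemExit("no pairs found; run analysis/02_code_states.py first")
    pairs = pd.read_csv(pairs_path)

    frames = []
    for sex in ("male", "female"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            models = mmle.fit_models(pairs, delta=2, stratum={"sex": sex})
        for w in caught:
            print(f"  [{sex}] note: {w.message}")
        parr = mmle.build_probability_array(models)
        frame = parr.to_frame()
        frame["sex"] = sex
        frames.append(frame)
        dead60 = {mmle.STATE_LABELS[o]: parr.at(60.0)[o, 4] for o in mmle.LIVING_STATES}
        print(f"{sex}: P(death within 2y at age 60) by origin:",
              {k: round(v, 4) for k, v in dead60.items()})

    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / "transition_probabilities.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False, float_format="%.6g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
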