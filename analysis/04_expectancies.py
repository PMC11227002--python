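#!/usr/bin/env python
"""Sex-specific state expectancies at age 60 with delta-method intervals.

Combines the fitted transition matrices with the survey-weighted 60-69
baseline distribution, averages conditional expectancies, and reports the
multimorbidity-free / multimorbid split of remaining life expectancy with
95% confidence intervals (lower bounds clamped at zero).
"""

import warnings
from pathlib import Path

import pandas as pd

import mmle

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main():
    for name in ("coded.csv", "pairs.csv"):
        if not (SCRATCH / name).exists():
            raise SystemExit("missing inputs; run analysis scripts 01 and 02 first")
    coded = pd.read_csv(SCRATCH / "coded.csv")
    pairs = pd.read_csv(SCRATCH / "pairs.csv")

    frames = []
    for sex in ("male", "female"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = mmle.fit_models(pairs, delta=2, stratum={"sex": sex})
            parr = mmle.build_probability_array(models)
            pi = mmle.estimate_initial_distribution(coded, stratum={"sex": sex})
            table = mmle.compute_expectancies(parr, pi)
            report = mmle.delta_ci(models, pi)
            mmle.attach_cis(table, report)
        frame = table.to_frame()
        frame["sex"] = sex
        frames.append(frame)
        print(f"\n{sex}: baseline 60-69 distribution pi = {pi.pi.round(3)}")
        print(frame.to_string(index=False, float_format=lambda x: f"{x:.1f}"))

    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / "expectancies.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False, float_format="%.6g")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
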