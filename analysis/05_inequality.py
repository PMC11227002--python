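#!/usr/bin/env python
"""Sex gaps and cumulative (dis)advantage across education groups.

Refits the models by sex and education, computes female-minus-male
multimorbid-life-expectancy gaps in the lowest and highest education groups,
and flags cumulative disadvantage (larger gap among the low-educated) or
cumulative advantage (the reverse).  Gap intervals assume independence
across strata, which are fitted on disjoint samples.
"""

import json
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

    mmle_by, reports = {}, {}
    for sex in ("male", "female"):
        for edu in mmle.EDUCATION_LEVELS:
            stratum = {"sex": sex, "education": edu}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models = mmle.fit_models(pairs, delta=2, stratum=stratum)
                parr = mmle.build_probability_array(models)
                pi = mmle.estimate_initial_distribution(coded, stratum=stratum)
                table = mmle.compute_expectancies(parr, pi)
                reports[(sex, edu)] = mmle.delta_ci(models, pi, quantities=("mmle",))
            mmle_by[(sex, edu)] = table.mmle
            print(f"{sex:>6} / {edu:<15} MMLE = {table.mmle:5.1f} years")

    cis = {}
    for tag, edu in (("low", "primary_or_less"), ("high", "postsecondary")):
        gap, lo, hi = mmle.sex_gap_ci(
            {sex: reports[(sex, edu)] for sex in ("male", "female")}, "mmle"
        )
        cis[tag] = (lo, hi)
        print(f"sex gap ({edu}): {gap:.1f} years (95% CI {lo:.1f} to {hi:.1f})")

    report = mmle.cumulative_disadvantage(mmle_by, label="mmle", cis=cis)
    verdict = (
        "cumulative disadvantage for low-educated women"
        if report.cumulative_disadvantage
        else "cumulative advantage for high-educated men"
        if report.cumulative_advantage
        else "tie"
    )
    print(f"gap_low = {report.gap_low:.2f}, gap_high = {report.gap_high:.2f} -> {verdict}")

    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / "inequality.json"
    out.write_text(json.dumps(report.as_dict(), indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
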