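#!/usr/bin/env python
"""Simulate a harmonized-survey-style panel from the ground-truth process.

Draws a sex-by-education stratified panel (2-year waves, entry at 60+,
state-independent 10% wave-on-wave attrition) from the survey-like scenario
and reports its basic structure: persons, person-waves, deaths observed,
retention.  The raw panel goes to scratch/ (it is an intermediate, not a
result); downstream scripts read it from there.
"""

import argparse
from pathlib import Path

import mmle

SCRATCH = Path("scratch/analysis")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-persons", type=int, default=12_000)
    ap.add_argument("--seed", type=int, default=2024)
    args = ap.parse_args()

    scenario = mmle.default_scenario(n_persons=args.n_persons, seed=args.seed)
    panel = mmle.emit_panel(scenario)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    out = SCRATCH / "panel.csv"
    mmle.write_panel(panel, out)

    persons = panel["person_id"].nunique()
    deaths = (panel["alive"] == 0).sum()
    waves = panel.groupby("person_id").size()
    print(f"wrote {out} ({len(panel)} person-waves, {persons} persons)")
    print(f"observed deaths: {deaths} ({100 * deaths / persons:.1f}% of persons)")
    print(f"waves per person: median {waves.median():.0f}, max {waves.max()}")
    by = panel[panel["wave"] == 0].groupby(["sex", "education"]).size()
    print("entry-wave stratum sizes:")
    print(by.to_string())


if __name__ == "__main__":
    main()
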