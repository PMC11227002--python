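"""Sex-gap and cumulative-(dis)advantage statistics over expectancy tables.

The headline inequality statistic subtracts male from female multimorbid life
expectancy (MMLE) within the lowest and highest education groups.  A larger
female-male gap among the low-educated than among the high-educated signals
cumulative disadvantage for low-educated women; the reverse signals
cumulative advantage for high-educated men.  Gaps are point comparisons with
independence-based confidence intervals (strata are fitted on disjoint
samples); no hypothesis test is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expectancy import ExpectancyTable, extract_quantity

LOW_EDU = "primary_or_less"
HIGH_EDU = "postsecondary"


class ReportingError(ValueError):
    pass


def sex_gap(tables_by_sex: dict, measure: str = "mmle") -> float:
    """Female value minus male value for the selected measure.

    ``tables_by_sex`` maps 'female'/'male' to ExpectancyTable objects or to
    plain floats already on the measure's scale.
    """
    for sex in ("female", "male"):
        if sex not in tables_by_sex:
            raise ReportingError(f"missing {sex} stratum for sex gap")

    def value(obj):
        if isinstance(obj, ExpectancyTable):
            return extract_quantity(obj, measure)
        return float(obj)

    return value(tables_by_sex["female"]) - value(tables_by_sex["male"])


def sex_gap_ci(reports_by_sex: dict, quantity: str = "mmle") -> tuple[float, float, float]:
    """Gap with a 95% interval under cross-stratum independence.

    ``reports_by_sex`` maps sex to a delta-method variance report frame.
    Returns (gap, lower, upper); gap bounds are not clamped at zero since
    differences may legitimately be negative.
    """
    vals = {}
    for sex in ("female", "male"):
        rep = reports_by_sex[sex]
        row = rep[rep["quantity"] == quantity]
        if row.empty:
            raise ReportingError(f"quantity {quantity!r} missing from {sex} report")
        vals[sex] = (float(row["estimate"].iloc[0]), float(row["se"].iloc[0]))
    gap = vals["female"][0] - vals["male"][0]
    se = float(np.hypot(vals["female"][1], vals["male"][1]))
    return gap, gap - 1.96 * se, gap + 1.96 * se


@dataclass
class InequalityReport:
    """Cumulative-(dis)advantage summary from education-extreme sex gaps."""

    gap_low: float
    gap_high: float
    cumulative_disadvantage: bool = field(init=False)
    cumulative_advantage: bool = field(init=False)
    tie: bool = field(init=False)
    sign_change: bool = field(init=False)
    gap_low_ci: tuple | None = None
    gap_high_ci: tuple | None = None
    label: str = ""

    def __post_init__(self):
        self.tie = self.gap_low == self.gap_high
        self.cumulative_disadvantage = self.gap_low > self.gap_high
        self.cumulative_advantage = self.gap_high > self.gap_low
        self.sign_change = (self.gap_low > 0) != (self.gap_high > 0)

    def as_dict(self) -> dict:
        return {
            "gap_low": self.gap_low,
            "gap_high": self.gap_high,
            "cumulative_disadvantage": self.cumulative_disadvantage,
            "cumulative_advantage": self.cumulative_advantage,
            "tie": self.tie,
            "sign_change": self.sign_change,
            "gap_low_ci": list(self.gap_low_ci) if self.gap_low_ci else None,
            "gap_high_ci": list(self.gap_high_ci) if self.gap_high_ci else None,
            "label": self.label,
        }


def cumulative_disadvantage(
    mmle_by_stratum: dict, label: str = "", cis: dict | None = None
) -> InequalityReport:
    """Build the report from MMLE values keyed by (sex, education).

    The middle education category plays no role in the statistic.  Missing
    cells raise with an explicit marker of which gap is not computable.
    """
    gaps = {}
    for edu, tag in ((LOW_EDU, "low"), (HIGH_EDU, "high")):
        cell = {}
        for sex in ("female", "male"):
            key = (sex, edu)
            if key not in mmle_by_stratum:
                raise ReportingError(f"gap_{tag} not computable: missing stratum {key}")
            cell[sex] = mmle_by_stratum[key]
        gaps[tag] = sex_gap(cell)
    report = InequalityReport(gap_low=gaps["low"], gap_high=gaps["high"], label=label)
    if cis:
        report.gap_low_ci = cis.get("low")
        report.gap_high_ci = cis.get("high")
    return report
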