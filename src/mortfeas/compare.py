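"""Side-by-side comparison of informant-method and survey ledgers.

The headline feasibility quantities are, per site and per quantity kind
(person-hours or US$):

    abs_difference = survey_total - informant_total
    pct_saving     = 100 x abs_difference / survey_total

A positive saving means the informant method is cheaper; negative means it
is costlier (which happens where population estimation dominates).  The
multi-site headline figure is the *unweighted* arithmetic mean of per-site
percentage savings — not a pooled-total percentage, which weights large
sites more heavily and gives a different number.

Also here: per-death efficiency (person-hours or US$ per death detected)
and the verbal-autopsy time budget (interview + analysis minutes per
questionnaire, expressed as a share of a site's total person-time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

from ._round import round_half_up
from .costing import CostLedger, Ledger, TimeLedger, UnitMismatchError, present_ledger


class NoDataError(ValueError):
    """No comparison rows to average."""


class NoDeathsError(ValueError):
    """Per-death efficiency is undefined with zero deaths."""


@dataclass(frozen=True)
class ComparisonRow:
    site_id: str
    quantity: str  # "time_hours" | "cost_usd"
    informant_total: float
    survey_total: float

    @property
    def abs_difference(self) -> float:
        return self.survey_total - self.informant_total

    @property
    def pct_saving(self) -> float:
        """Percent of the survey total saved by the informant method."""
        return 100.0 * self.abs_difference / self.survey_total

    @property
    def pct_saving_presented(self) -> int:
        return int(round_half_up(self.pct_saving))


@dataclass(frozen=True)
class VABudget:
    n_questionnaires: int
    interview_minutes_each: float
    analysis_minutes_each: float
    site_total_hours: float

    @property
    def total_hours(self) -> float:
        return (
            self.n_questionnaires
            * (self.interview_minutes_each + self.analysis_minutes_each)
            / 60.0
        )

    @property
    def share_of_site_total(self) -> float:
        return 100.0 * self.total_hours / self.site_total_hours


def _quantity_of(ledger: Ledger) -> str:
    if isinstance(ledger, TimeLedger):
        return "time_hours"
    if isinstance(ledger, CostLedger):
        return "cost_usd"
    raise UnitMismatchError(f"unsupported ledger type: {type(ledger).__name__}")


def compare(
    informant: Union[Ledger, float],
    survey: Union[Ledger, float],
    site_id: str = "",
    quantity: str = "time_hours",
) -> ComparisonRow:
    """Compare informant-method and survey totals of the same quantity.

    Accepts either ledgers (totals are taken) or pre-computed totals
    (e.g. a published table's as-printed grand totals).
    """
    if isinstance(informant, Ledger) or isinstance(survey, Ledger):
        if not (isinstance(informant, Ledger) and isinstance(survey, Ledger)):
            raise UnitMismatchError("compare two ledgers or two totals, not a mix")
        qi, qs = _quantity_of(informant), _quantity_of(survey)
        if qi != qs:
            raise UnitMismatchError(f"quantity mismatch: {qi} vs {qs}")
        return ComparisonRow(site_id, qi, informant.grand_total(), survey.grand_total())
    return ComparisonRow(site_id, quantity, float(informant), float(survey))


def mean_saving(rows: Sequence[ComparisonRow]) -> float:
    """Unweighted mean of per-site percentage savings (full precision)."""
    rows = list(rows)
    if not rows:
        raise NoDataError("no comparison rows")
    quantities = {r.quantity for r in rows}
    if len(quantities) != 1:
        raise UnitMismatchError(f"mixed quantities in mean_saving: {sorted(quantities)}")
    return sum(r.pct_saving for r in rows) / len(rows)


def per_death(total: float, deaths: int) -> float:
    """Person-hours or US$ consumed per death detected."""
    if deaths <= 0:
        raise NoDeathsError("deaths must be positive")
    return total / deaths


def va_budget(
    n_questionnaires: int,
    interview_minutes_each: float,
    analysis_minutes_each: float,
    site_total_hours: float,
) -> VABudget:
    """Verbal-autopsy time budget and its share of a site's person-time."""
    if n_questionnaires < 0 or interview_minutes_each < 0 or analysis_minutes_each < 0:
        raise ValueError("counts and durations must be >= 0")
    if site_total_hours <= 0:
        raise ValueError("site_total_hours must be positive")
    return VABudget(
        n_questionnaires, interview_minutes_each, analysis_minutes_each, site_total_hours
    )


def comparison_frame(rows: Iterable[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a tidy table (presentation rounding applied)."""
    data = [
        {
            "site_id": r.site_id,
            "quantity": r.quantity,
            "informant_total": round_half_up(r.informant_total),
            "survey_total": round_half_up(r.survey_total),
            "abs_difference": round_half_up(r.abs_difference),
            "pct_saving": r.pct_saving_presented,
        }
        for r in rows
    ]
    return pd.DataFrame(
        data,
        columns=[
            "site_id",
            "quantity",
            "informant_total",
            "survey_total",
            "abs_difference",
            "pct_saving",
        ],
    )


def render_report(
    ledgers: dict[str, dict[str, Ledger]],
    rows: Sequence[ComparisonRow] = (),
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Render activity-margin and role-margin tables plus a summary.

    ``ledgers`` maps site_id -> {method_label -> Ledger}.  Returns (and
    optionally writes as CSV) three frames: ``by_activity`` (Table-4
    style), ``by_role`` (Table-5 style), and ``comparison``.  Ordering is
    deterministic: sites and methods in sorted order, activities/roles in
    their canonical order of appearance.
    """
    by_activity_parts = []
    by_role_parts = []
    for site_id in sorted(ledgers):
        for method in sorted(ledgers[site_id]):
            ledger = ledgers[site_id][method]
            wide = present_ledger(ledger)
            if wide.empty:
                continue
            long = wide.drop(columns="total").stack().rename(ledger.unit).reset_index()
            long.insert(0, "site_id", site_id)
            long.insert(1, "method", method)
            by_activity_parts.append(long)
            roles = pd.DataFrame(
                sorted(ledger.role_totals().items()), columns=["role", ledger.unit]
            )
            roles[ledger.unit] = roles[ledger.unit].map(round_half_up)
            roles.insert(0, "site_id", site_id)
            roles.insert(1, "method", method)
            by_role_parts.append(roles)

    empty_activity = pd.DataFrame(
        columns=["site_id", "method", "activity", "role", "value"]
    )
    empty_role = pd.DataFrame(columns=["site_id", "method", "role", "value"])
    report = {
        "by_activity": (
            pd.concat(by_activity_parts, ignore_index=True)
            if by_activity_parts
            else empty_activity
        ),
        "by_role": (
            pd.concat(by_role_parts, ignore_index=True) if by_role_parts else empty_role
        ),
        "comparison": comparison_frame(rows),
    }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in report.items():
            frame.to_csv(out / f"{name}.csv", index=False)
    return report
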