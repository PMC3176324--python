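"""Activity-based micro-costing of field mortality-measurement exercises.

A field exercise (an informant-method implementation, or a hypothetical
retrospective survey) decomposes into activities — preparation, population
estimation, focus-group discussion, training, data collection, data
entry/analysis, report production — each consuming person-time from staff
roles (investigators, data collectors, drivers, collaborators, other
staff) and from the community (respondents, key informants, FGD
participants, who are not paid).

Time consumption is expressed as declarative *time rules* evaluated
against a survey scenario (number of households, clusters, interviewers):

* ``fixed_team_days`` — n staff x days x hours/day (working day = 8 h);
* ``per_household`` — minutes per household interview, optionally accrued
  per staff member present when households are interviewed by a team;
* ``per_new_household_selection`` — minutes to select each new household;
* ``per_cluster`` — hours per cluster (preparation or driving);
* ``per_questionnaire_entry`` — entry minutes per questionnaire, inflated
  by a double-entry fraction;
* ``per_informant`` — key-informant contact time;
* ``respondent_time`` — unpaid respondent time per household;
* ``proportional`` — a role's hours as a multiple (and/or division) of
  another role's hours within the same activity, e.g. "2 drivers x
  person-time for study investigators";
* ``observed_copy`` — take the activity's rows verbatim from an observed
  ledger (e.g. survey preparation assumed identical to the observed
  informant-method preparation).

Evaluation yields a :class:`TimeLedger` (activity x role person-hours);
:func:`price_ledger` converts it to a :class:`CostLedger` in US$ using
hourly staff rates, with unpaid community roles priced at zero and one-off
lump-sum payments added to their activity cell.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from ._round import round_half_up

HOURS_PER_DAY = 8.0  # working day

ACTIVITIES = (
    "preparation",
    "population_estimation",
    "fgd",
    "training",
    "data_collection",
    "data_entry_analysis",
    "report",
)

ROLES = (
    "investigator",
    "other_staff",
    "collaborator",
    "data_collector",
    "driver",
    "respondent",
    "fgd_participant",
    "key_informant",
    "field_team",  # aggregate pseudo-role for as-printed observed ledgers
)

UNPAID_ROLES = frozenset({"respondent", "fgd_participant", "key_informant"})


class MissingObservedError(ValueError):
    """A scenario uses observed_copy but no observed ledger was supplied."""


class DependencyCycleError(ValueError):
    """Proportional time rules form a cycle."""


class MissingRateError(KeyError):
    """A ledger role has no staff rate."""


class MalformedRecordError(ValueError):
    """An observed time record has a negative duration or unknown field."""


class UnitMismatchError(TypeError):
    """Two ledgers of different quantity kinds were combined."""


# ---------------------------------------------------------------------------
# ledgers


class Ledger:
    """Sparse activity x role table of non-negative quantities.

    Totals over either margin (activities or roles) equal the grand total
    by construction; this conservation is what makes the Table-style
    reports internally consistent.
    """

    unit = "quantity"

    def __init__(self, entries: Optional[Mapping[tuple[str, str], float]] = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (activity, role), value in entries.items():
                self.add(activity, role, value)

    def add(self, activity: str, role: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative ledger entry: {activity}/{role} = {value}")
        key = (activity, role)
        self._entries[key] = self._entries.get(key, 0.0) + float(value)

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        return dict(self._entries)

    def get(self, activity: str, role: str) -> float:
        return self._entries.get((activity, role), 0.0)

    def activity_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (activity, _), v in self._entries.items():
            out[activity] = out.get(activity, 0.0) + v
        return out

    def role_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (_, role), v in self._entries.items():
            out[role] = out.get(role, 0.0) + v
        return out

    def grand_total(self) -> float:
        return sum(self._entries.values())

    def activity_rows(self, activity: str) -> dict[str, float]:
        return {r: v for (a, r), v in self._entries.items() if a == activity}

    def scaled(self, factor: float):
        out = type(self)()
        for (a, r), v in self._entries.items():
            out.add(a, r, v * factor)
        return out

    def merged(self, other: "Ledger"):
        if type(other) is not type(self):
            raise UnitMismatchError(
                f"cannot merge {type(self).__name__} with {type(other).__name__}"
            )
        out = type(self)(self._entries)
        for (a, r), v in other._entries.items():
            out.add(a, r, v)
        return out

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        rows = [
            {
                "activity": a,
                "role": r,
                self.unit: round_half_up(v) if rounded else v,
            }
            for (a, r), v in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["activity", "role", self.unit])

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}(total={self.grand_total():.1f} {self.unit})"


class TimeLedger(Ledger):
    unit = "person_hours"


class CostLedger(Ledger):
    unit = "usd"


# ---------------------------------------------------------------------------
# staff rates and currency


@dataclass(frozen=True)
class StaffRate:
    role: str
    hourly_usd: float = 0.0
    lump_sum_usd: float = 0.0
    lump_activity: str = "population_estimation"
    paid: bool = True

    def __post_init__(self) -> None:
        if self.hourly_usd < 0 or self.lump_sum_usd < 0:
            raise ValueError("rates must be non-negative")
        if self.role in UNPAID_ROLES and self.paid:
            object.__setattr__(self, "paid", False)


@dataclass(frozen=True)
class ExchangeRate:
    currency_code: str
    units_per_usd: float
    as_of: str = ""

    def __post_init__(self) -> None:
        if self.units_per_usd <= 0:
            raise ValueError("units_per_usd must be positive")


def convert_currency(amount_local: float, rate: ExchangeRate) -> float:
    """Local-currency amount to US$ at the given exchange rate."""
    return amount_local / rate.units_per_usd


# ---------------------------------------------------------------------------
# time rules (tagged union)


@dataclass(frozen=True)
class FixedTeamDays:
    role: str
    n_staff: int
    days: float
    hours_per_day: float = HOURS_PER_DAY

    def hours(self, scenario: "SurveyScenario") -> float:
        return self.n_staff * self.days * self.hours_per_day


@dataclass(frozen=True)
class PerHousehold:
    role: str
    minutes_per_household: float
    staff_per_household: int = 1

    def hours(self, scenario: "SurveyScenario") -> float:
        return (
            scenario.n_households
            * self.minutes_per_household
            * self.staff_per_household
            / 60.0
        )


@dataclass(frozen=True)
class PerNewHouseholdSelection:
    role: str
    minutes: float

    def hours(self, scenario: "SurveyScenario") -> float:
        return scenario.n_households * self.minutes / 60.0


@dataclass(frozen=True)
class PerCluster:
    role: str
    hours_per_cluster: float
    applies: str = "preparation"  # "preparation" | "driving"

    def hours(self, scenario: "SurveyScenario") -> float:
        return scenario.n_clusters * self.hours_per_cluster


@dataclass(frozen=True)
class PerQuestionnaireEntry:
    role: str
    minutes_per_questionnaire: float
    double_entry_fraction: float = 0.0

    def hours(self, scenario: "SurveyScenario") -> float:
        if not 0 <= self.double_entry_fraction <= 1:
            raise ValueError("double_entry_fraction must be in [0, 1]")
        return (
            scenario.n_households
            * self.minutes_per_questionnaire
            * (1.0 + self.double_entry_fraction)
            / 60.0
        )


@dataclass(frozen=True)
class PerInformant:
    n_informants: int
    minutes_each: float
    role: str = "key_informant"

    def hours(self, scenario: "SurveyScenario") -> float:
        return self.n_informants * self.minutes_each / 60.0


@dataclass(frozen=True)
class RespondentTime:
    minutes_per_household: float
    role: str = "respondent"

    def hours(self, scenario: "SurveyScenario") -> float:
        return scenario.n_households * self.minutes_per_household / 60.0


@dataclass(frozen=True)
class Proportional:
    """role hours = factor x (source role's hours in this activity) / divisor."""

    role: str
    source: str
    factor: float = 1.0
    divisor: Optional[float] = None


@dataclass(frozen=True)
class ObservedCopy:
    """Copy this activity's rows verbatim from the observed ledger."""

    activity: Optional[str] = None  # defaults to the activity it appears under


TimeRule = Union[
    FixedTeamDays,
    PerHousehold,
    PerNewHouseholdSelection,
    PerCluster,
    PerQuestionnaireEntry,
    PerInformant,
    RespondentTime,
    Proportional,
    ObservedCopy,
]

_RULE_TYPES = {
    "fixed_team_days": FixedTeamDays,
    "per_household": PerHousehold,
    "per_new_household_selection": PerNewHouseholdSelection,
    "per_cluster": PerCluster,
    "per_questionnaire_entry": PerQuestionnaireEntry,
    "per_informant": PerInformant,
    "respondent_time": RespondentTime,
    "proportional": Proportional,
    "observed_copy": ObservedCopy,
}


def rule_from_dict(spec: Mapping) -> TimeRule:
    spec = dict(spec)
    kind = spec.pop("rule")
    try:
        cls = _RULE_TYPES[kind]
    except KeyError:
        raise ValueError(f"unknown time rule: {kind!r}") from None
    return cls(**spec)


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class SurveyScenario:
    """One survey design plus its Table-of-assumptions time rules."""

    site_id: str
    n_households: int
    n_clusters: int = 0  # 0 for linear systematic sampling
    n_interviewers: int = 0
    team_size: int = 1
    n_key_informants: int = 0
    recall_label: str = ""
    activity_plans: dict[str, list[TimeRule]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (
            ("n_households", self.n_households),
            ("n_clusters", self.n_clusters),
            ("n_interviewers", self.n_interviewers),
            ("n_key_informants", self.n_key_informants),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for activity in self.activity_plans:
            if activity not in ACTIVITIES:
                raise ValueError(f"unknown activity: {activity!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SurveyScenario":
        data = dict(data)
        plans = {
            activity: [rule_from_dict(r) for r in rules]
            for activity, rules in data.pop("activities", {}).items()
        }
        return cls(activity_plans=plans, **data)

    @classmethod
    def from_yaml(cls, path) -> "SurveyScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _toposort_proportional(rules: Sequence[Proportional]) -> list[Proportional]:
    """Order proportional rules so every source is computed first."""
    targets = {r.role for r in rules}
    remaining = list(rules)
    ordered: list[Proportional] = []
    resolved: set[str] = set()
    while remaining:
        progress = False
        for r in list(remaining):
            if r.source not in targets or r.source in resolved:
                ordered.append(r)
                resolved.add(r.role)
                remaining.remove(r)
                progress = True
        if not progress:
            cycle = sorted({r.role for r in remaining})
            raise DependencyCycleError(f"cyclic proportional rules among roles {cycle}")
    return ordered


def evaluate_scenario(
    scenario: SurveyScenario,
    observed: Optional[TimeLedger] = None,
) -> TimeLedger:
    """Evaluate a scenario's time rules into a person-hour ledger.

    Non-proportional rules are evaluated first; proportional rules then run
    in dependency order within each activity (a cycle is an error).
    ``observed`` is required iff any ``observed_copy`` rule is present.
    """
    ledger = TimeLedger()
    for activity, rules in scenario.activity_plans.items():
        proportional = [r for r in rules if isinstance(r, Proportional)]
        for rule in rules:
            if isinstance(rule, Proportional):
                continue
            if isinstance(rule, ObservedCopy):
                if observed is None:
                    raise MissingObservedError(
                        f"activity {activity!r} copies observed rows but no "
                        "observed ledger was supplied"
                    )
                source_activity = rule.activity or activity
                for role, hours in observed.activity_rows(source_activity).items():
                    ledger.add(activity, role, hours)
                continue
            ledger.add(activity, rule.role, rule.hours(scenario))
        for rule in _toposort_proportional(proportional):
            hours = rule.factor * ledger.get(activity, rule.source)
            if rule.divisor:
                hours /= rule.divisor
            ledger.add(activity, rule.role, hours)
    return ledger


# ---------------------------------------------------------------------------
# pricing


def price_ledger(
    time: TimeLedger,
    rates: Mapping[str, StaffRate],
    hours_rounding: str = "none",
) -> CostLedger:
    """Price a time ledger in US$.

    Paid roles cost ``person_hours x hourly_usd``; unpaid community roles
    (respondents, FGD participants, key informants) cost $0; lump sums are
    added once to their (activity, role) cell when that cell has hours.

    ``hours_rounding="cell"`` rounds each (activity, role) person-hour cell
    half-up to whole hours before pricing — the convention under which
    published cost tables priced from pre-rounded hour cells are
    reproduced.  The default prices full-precision hours.
    """
    if hours_rounding not in ("none", "cell"):
        raise ValueError("hours_rounding must be 'none' or 'cell'")
    cost = CostLedger()
    lump_added: set[str] = set()
    for (activity, role), hours in time.entries.items():
        if role in UNPAID_ROLES:
            cost.add(activity, role, 0.0)
            continue
        try:
            rate = rates[role]
        except KeyError:
            raise MissingRateError(f"no staff rate for role {role!r}") from None
        if hours_rounding == "cell":
            hours = round_half_up(hours)
        usd = hours * rate.hourly_usd if rate.paid else 0.0
        if rate.lump_sum_usd and activity == rate.lump_activity and role not in lump_added:
            usd += rate.lump_sum_usd
            lump_added.add(role)
        cost.add(activity, role, usd)
    return cost


def project_survey(
    scenario: SurveyScenario,
    rates: Mapping[str, StaffRate],
    observed_time: Optional[TimeLedger] = None,
    observed_cost: Optional[CostLedger] = None,
    hours_rounding: str = "cell",
) -> tuple[TimeLedger, CostLedger]:
    """Project a survey scenario into time and cost ledgers.

    Activities copied verbatim from the observed exercise (``observed_copy``
    rules) take both their hours and their US$ from the observed ledgers;
    everything else is rule-evaluated and priced with the site's staff
    rates.  The default ``hours_rounding="cell"`` matches how published
    cost tables were priced (from hour cells rounded to the whole hour).
    """
    time = evaluate_scenario(scenario, observed=observed_time)
    copied = {
        activity
        for activity, rules in scenario.activity_plans.items()
        if any(isinstance(r, ObservedCopy) for r in rules)
    }
    if copied and observed_cost is None:
        raise MissingObservedError(
            "scenario copies observed activities but no observed cost ledger given"
        )
    rule_time = TimeLedger(
        {k: v for k, v in time.entries.items() if k[0] not in copied}
    )
    cost = price_ledger(rule_time, rates, hours_rounding=hours_rounding)
    for activity in copied:
        for role, usd in observed_cost.activity_rows(activity).items():
            cost.add(activity, role, usd)
    return time, cost


# ---------------------------------------------------------------------------
# observed-ledger ingestion

_UNIT_TO_HOURS = {
    "h": 1.0,
    "hr": 1.0,
    "hour": 1.0,
    "hours": 1.0,
    "min": 1 / 60.0,
    "minute": 1 / 60.0,
    "minutes": 1 / 60.0,
    "day": HOURS_PER_DAY,
    "days": HOURS_PER_DAY,
}


def ingest_observed(records: Union[pd.DataFrame, str, Iterable[Mapping]]) -> TimeLedger:
    """Aggregate observed (activity, role, duration, unit) rows into a ledger.

    Accepts a CSV path, a DataFrame, or an iterable of mappings.  Durations
    may be given as ``duration`` + ``unit`` (h/min/day) or as ``hours`` and
    ``minutes`` columns recorded separately in the field.
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "read"):
        df = pd.read_csv(records)
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        return TimeLedger()

    ledger = TimeLedger()
    for row in df.to_dict("records"):
        activity = str(row["activity"])
        role = str(row["role"])
        if activity not in ACTIVITIES:
            raise MalformedRecordError(f"unknown activity: {activity!r}")
        if role not in ROLES:
            raise MalformedRecordError(f"unknown role: {role!r}")
        hours = 0.0
        if row.get("duration") is not None and not pd.isna(row.get("duration")):
            unit = str(row.get("unit", "h")).strip().lower()
            if unit not in _UNIT_TO_HOURS:
                raise MalformedRecordError(f"unknown duration unit: {unit!r}")
            hours = float(row["duration"]) * _UNIT_TO_HOURS[unit]
        else:
            h = float(row.get("hours", 0) or 0)
            m = float(row.get("minutes", 0) or 0)
            hours = h + m / 60.0
        if hours < 0:
            raise MalformedRecordError(f"negative duration for {activity}/{role}")
        ledger.add(activity, role, hours)
    return ledger


# ---------------------------------------------------------------------------
# presentation


def present_ledger(ledger: Ledger) -> pd.DataFrame:
    """Activity x role table with cells rounded half-up to whole units."""
    df = ledger.to_frame(rounded=True)
    if df.empty:
        return df
    wide = df.pivot_table(
        index="activity", columns="role", values=ledger.unit, aggfunc="sum", fill_value=0
    )
    wide["total"] = wide.sum(axis=1)
    return wide


def presented_activity_totals(ledger: Ledger) -> dict[str, float]:
    """Activity totals rounded half-up to whole units, per activity cell.

    Published summary tables round each activity cell and sum the rounded
    cells; 329.5 raw data-collection hours present as 330 and enter the
    grand total as 330.
    """
    return {a: round_half_up(v) for a, v in ledger.activity_totals().items()}


def presented_total(ledger: Ledger) -> float:
    """Grand total summed from rounded activity cells."""
    return round_half_up(sum(presented_activity_totals(ledger).values()))
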