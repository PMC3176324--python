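"""Packaged study-site fixtures and assumption configs.

Ships the four field sites' published inputs so the whole pipeline runs
with no external data:

* ``study_sites.csv`` — population denominators (total / under-5), recall
  window, sector counts, detected deaths, and reference sensitivities;
* ``activity_ledgers_as_printed.csv`` / ``role_ledgers_as_printed.csv`` —
  observed informant-method ledgers and projected survey ledgers exactly
  as published (activity and staff-type margins);
* ``ledger_totals_as_printed.csv`` — the published grand totals (these
  occasionally differ by 1 unit from the sum of published cells, a
  rounding artefact of the source tables; both views are shipped);
* ``staff_rates.yaml`` — hourly US$ staff costs and exchange rates;
* ``scenarios/*.yaml`` — declarative survey time-rule assumptions per
  site and recall period.

Observed ledgers are at activity granularity with the aggregate
pseudo-role ``field_team`` (the per-role split of each activity was not
published); the role-margin view lives in the role ledger fixture.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Optional

import pandas as pd
import yaml

from .costing import CostLedger, ExchangeRate, StaffRate, SurveyScenario, TimeLedger
from .rates import SiteFrame

SITES = ("kabul", "mae_la", "chiradzulu", "tanzania")
METHODS = ("informant", "survey_6mo", "survey_30d")

_DATA = files("mortfeas") / "data"


def data_path(name: str):
    return _DATA / name


def load_site_table() -> pd.DataFrame:
    """Site denominators, deaths and sensitivities, one row per site."""
    return pd.read_csv(data_path("study_sites.csv"))


def load_site_frames() -> dict[str, SiteFrame]:
    frames = {}
    for row in load_site_table().itertuples(index=False):
        frames[row.site_id] = SiteFrame(
            site_id=row.site_id,
            population_total=int(row.population_total),
            population_under5=int(row.population_under5),
            recall_days=int(row.recall_days),
            n_sectors=int(row.n_sectors),
            label=row.label,
        )
    return frames


def _ledgers_from(df: pd.DataFrame, key: str, role: Optional[str] = None):
    time, cost = TimeLedger(), CostLedger()
    for row in df.itertuples(index=False):
        r = role or row.role
        time.add(getattr(row, key), r, float(row.hours))
        cost.add(getattr(row, key), r, float(row.usd))
    return time, cost


def load_observed_ledgers(site_id: str) -> tuple[TimeLedger, CostLedger]:
    """Observed informant-method ledgers (as printed, activity margin)."""
    return load_printed_ledgers(site_id, "informant")


def load_printed_ledgers(site_id: str, method: str) -> tuple[TimeLedger, CostLedger]:
    """As-printed activity-margin ledgers for one site and method."""
    df = pd.read_csv(data_path("activity_ledgers_as_printed.csv"))
    df = df[(df.site_id == site_id) & (df.method == method)]
    if df.empty:
        raise KeyError(f"no printed ledger for site={site_id!r} method={method!r}")
    return _ledgers_from(df, "activity", role="field_team")


def load_printed_role_ledgers(site_id: str, method: str) -> pd.DataFrame:
    """As-printed staff-type margin (hours and US$ per role)."""
    df = pd.read_csv(data_path("role_ledgers_as_printed.csv"))
    df = df[(df.site_id == site_id) & (df.method == method)]
    if df.empty:
        raise KeyError(f"no printed role ledger for site={site_id!r} method={method!r}")
    return df.reset_index(drop=True)


def load_printed_totals() -> pd.DataFrame:
    """Published grand totals per site and method (hours, US$)."""
    return pd.read_csv(data_path("ledger_totals_as_printed.csv"))


def printed_total(site_id: str, method: str, quantity: str = "hours") -> float:
    df = load_printed_totals()
    row = df[(df.site_id == site_id) & (df.method == method)]
    if row.empty:
        raise KeyError(f"no printed total for site={site_id!r} method={method!r}")
    return float(row.iloc[0][quantity])


def load_staff_rates(site_id: str) -> tuple[dict[str, StaffRate], ExchangeRate]:
    """Hourly rates (plus unpaid community roles) and the exchange rate."""
    with (data_path("staff_rates.yaml")).open() as fh:
        config = yaml.safe_load(fh)
    try:
        site = config["sites"][site_id]
    except KeyError:
        raise KeyError(f"no staff rates for site {site_id!r}") from None
    rates = {
        role: StaffRate(role=role, **params)
        for role, params in site["rates"].items()
    }
    for role in ("respondent", "fgd_participant", "key_informant"):
        rates[role] = StaffRate(role=role, hourly_usd=0.0, paid=False)
    cur = site["currency"]
    fx = ExchangeRate(cur["code"], float(cur["units_per_usd"]), str(cur["as_of"]))
    return rates, fx


def load_scenario(site_id: str, recall: str) -> SurveyScenario:
    """Survey scenario config for a site and recall period ('6mo'/'30d')."""
    path = _DATA / "scenarios" / f"{site_id}_survey_{recall}.yaml"
    with path.open() as fh:
        return SurveyScenario.from_dict(yaml.safe_load(fh))
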