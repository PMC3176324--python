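"""Crude and under-five mortality rates from death listings.

Mortality in acute settings is conventionally expressed as deaths per
10,000 persons per day (CMR) and, for children under five, deaths per
10,000 under-fives per day (U5MR).  The denominator here is a *period*
person-time: the site population held constant over the recall window,

    person_days = population_of_stratum x recall_days

with no half person-time deduction for decedents and no migration
adjustment — the convention under which a death listing and a population
frame reproduce the rates a field report prints.

The module also computes detection sensitivity of a death-ascertainment
method against an external reference count (e.g. a capture-recapture best
estimate, taken as a given input).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from ._round import round_half_up

PER = 10_000.0  # rate scale: deaths per 10,000 person-days


class Stratum(str, enum.Enum):
    all_ages = "all_ages"
    under5 = "under5"


class AgeClass(str, enum.Enum):
    under5 = "under5"
    five_plus = "five_plus"


class ReferralSource(str, enum.Enum):
    key_informant = "key_informant"
    household_snowball = "household_snowball"


class EmptyDenominatorError(ValueError):
    """Person-time denominator is zero."""


class UndefinedSensitivityError(ValueError):
    """Reference death count is zero; sensitivity is undefined."""


@dataclass(frozen=True)
class SiteFrame:
    """A site's population denominator and recall window.

    ``n_sectors`` counts the administrative units the exhaustive search is
    organised by (guzars, camp sections, villages, zones).
    """

    site_id: str
    population_total: int
    population_under5: int
    recall_days: int = 60
    n_sectors: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.population_under5 <= self.population_total):
            raise ValueError(
                "need 0 <= population_under5 <= population_total, got "
                f"{self.population_under5} / {self.population_total}"
            )
        if self.recall_days <= 0:
            raise ValueError("recall_days must be positive")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")

    def population(self, stratum: Stratum | str) -> int:
        stratum = Stratum(stratum)
        if stratum is Stratum.all_ages:
            return self.population_total
        return self.population_under5


@dataclass(frozen=True)
class DecedentRecord:
    """One detected death with referral provenance."""

    site_id: str
    death_date: date
    age_class: AgeClass
    sex: str = "unknown"
    cause_text: str = ""
    place_text: str = ""
    referral_source: ReferralSource = ReferralSource.key_informant
    household_id: str = ""


@dataclass(frozen=True)
class MortalityEstimate:
    deaths: int
    person_days: float
    rate: float  # deaths per 10,000 person-days
    stratum: Stratum = Stratum.all_ages
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def rate_presented(self) -> float:
        """Rate rounded half-up to 2 decimals (presentation only)."""
        return round_half_up(self.rate, 2)


def person_time(frame: SiteFrame, stratum: Stratum | str = Stratum.all_ages) -> float:
    """Period person-days: stratum population x recall days."""
    try:
        stratum = Stratum(stratum)
    except ValueError as exc:
        raise ValueError(f"unknown stratum: {stratum!r}") from exc
    return float(frame.population(stratum) * frame.recall_days)


def mortality_rate(
    deaths: int,
    person_days: float,
    stratum: Stratum | str = Stratum.all_ages,
    ci: bool = False,
    alpha: float = 0.05,
) -> MortalityEstimate:
    """Rate per 10,000 person-days; full precision retained internally.

    ``ci=True`` attaches an exact (Garwood) Poisson interval on the death
    count.  This is an extension for new analyses, not the interval method
    behind any published table of informant-method rates.
    """
    if person_days <= 0:
        raise EmptyDenominatorError("person_days must be positive")
    if deaths < 0:
        raise ValueError("deaths must be >= 0")
    rate = deaths / person_days * PER
    lo = hi = None
    if ci:
        lo = (stats.chi2.ppf(alpha / 2, 2 * deaths) / 2 if deaths > 0 else 0.0)
        hi = stats.chi2.ppf(1 - alpha / 2, 2 * deaths + 2) / 2
        lo = lo / person_days * PER
        hi = hi / person_days * PER
    return MortalityEstimate(deaths, float(person_days), rate, Stratum(stratum), lo, hi)


def detection_sensitivity(detected: int, reference: int) -> float:
    """Percent of reference deaths that the method detected.

    May exceed 100 when ``detected > reference``; the value is returned
    unclamped so the caller can flag it.
    """
    if reference <= 0:
        raise UndefinedSensitivityError("reference death count must be positive")
    if detected < 0:
        raise ValueError("detected must be >= 0")
    return 100.0 * detected / reference


def site_estimates(
    frame: SiteFrame,
    records: Iterable[DecedentRecord],
    ci: bool = False,
) -> dict[Stratum, MortalityEstimate]:
    """CMR and U5MR for one site from its death listing."""
    records = [r for r in records if r.site_id == frame.site_id]
    deaths_all = len(records)
    deaths_u5 = sum(1 for r in records if AgeClass(r.age_class) is AgeClass.under5)
    return {
        Stratum.all_ages: mortality_rate(
            deaths_all, person_time(frame, Stratum.all_ages), Stratum.all_ages, ci=ci
        ),
        Stratum.under5: mortality_rate(
            deaths_u5, person_time(frame, Stratum.under5), Stratum.under5, ci=ci
        ),
    }


def pooled_rate(estimates: Sequence[MortalityEstimate]) -> MortalityEstimate:
    """Rate over pooled sites: sum of deaths over sum of person-days."""
    if not estimates:
        raise ValueError("no estimates to pool")
    strata = {e.stratum for e in estimates}
    if len(strata) != 1:
        raise ValueError("cannot pool estimates across strata")
    deaths = sum(e.deaths for e in estimates)
    pdays = sum(e.person_days for e in estimates)
    return mortality_rate(deaths, pdays, strata.pop())


# ---------------------------------------------------------------------------
# tabular I/O


def read_death_listing(path) -> list[DecedentRecord]:
    """Read a death-listing CSV (one row per decedent, ISO-8601 dates)."""
    df = pd.read_csv(path, dtype=str)
    required = {"site_id", "death_date", "age_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"death listing missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DecedentRecord(
                site_id=row.site_id,
                death_date=date.fromisoformat(row.death_date),
                age_class=AgeClass(row.age_class),
                sex=getattr(row, "sex", "unknown") or "unknown",
                cause_text=getattr(row, "cause_text", "") or "",
                place_text=getattr(row, "place_text", "") or "",
                referral_source=ReferralSource(
                    getattr(row, "referral_source", "key_informant") or "key_informant"
                ),
                household_id=getattr(row, "household_id", "") or "",
            )
        )
    return records


def read_site_frames(path) -> list[SiteFrame]:
    df = pd.read_csv(path)
    return [
        SiteFrame(
            site_id=str(row.site_id),
            population_total=int(row.population_total),
            population_under5=int(row.population_under5),
            recall_days=int(getattr(row, "recall_days", 60)),
            n_sectors=int(getattr(row, "n_sectors", 1)),
            label=str(getattr(row, "label", "") or ""),
        )
        for row in df.itertuples(index=False)
    ]


def rates_table(
    frames: Sequence[SiteFrame],
    records: Iterable[DecedentRecord],
    ci: bool = False,
) -> pd.DataFrame:
    """One row per site: deaths, person-days, CMR and U5MR (presented)."""
    records = list(records)
    rows = []
    for frame in frames:
        est = site_estimates(frame, records, ci=ci)
        cmr, u5 = est[Stratum.all_ages], est[Stratum.under5]
        rows.append(
            {
                "site_id": frame.site_id,
                "population_total": frame.population_total,
                "population_under5": frame.population_under5,
                "recall_days": frame.recall_days,
                "deaths": cmr.deaths,
                "deaths_under5": u5.deaths,
                "cmr": cmr.rate_presented,
                "u5mr": u5.rate_presented,
            }
        )
    return pd.DataFrame(rows)
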