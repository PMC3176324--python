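"""Sample-size projection for retrospective mortality surveys.

A retrospective mortality survey estimates a crude mortality rate (CMR,
deaths per 10,000 person-days) from the deaths reported by a household
sample over a recall period.  On the period scale, each person carries a
death risk

    p = CMR x recall_days / 10,000

and the survey must estimate p to a stated precision d (absolute, or a
fraction of p).  With a normal approximation the required number of
persons is

    n = DEFF x z^2 x V / d^2

where V = p under a Poisson (rare-event) variance model or p(1 - p) under
a binomial model, DEFF is the design effect of cluster sampling, and z is
the standard-normal quantile for the confidence level.  Households follow
by dividing by the mean household size.

The Poisson variance model with z = 1.96 is the default: it is the form
under which the standard worked sample sizes for humanitarian (SMART-style)
mortality surveys come out exactly.  Household counts are truncated to a
whole household (see ``round_households``), which is likewise the only
convention consistent with all of those worked values at z = 1.96.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

from ._round import int_half_up

PER = 10_000.0


class VarianceModel(str, enum.Enum):
    poisson = "poisson"
    binomial = "binomial"


class InvalidRiskError(ValueError):
    """Period death risk >= 1 under the binomial model."""


class ZeroPrecisionError(ValueError):
    """Requested precision is zero."""


@dataclass(frozen=True)
class SurveyDesignSpec:
    """Design assumptions for one sample-size computation.

    precision is interpreted on the rate scale (deaths per 10,000
    person-days) when ``precision_kind`` is "absolute", or as a fraction
    of ``expected_cmr`` when "relative".
    """

    expected_cmr: float
    recall_days: float
    precision: float
    precision_kind: str = "absolute"  # "absolute" | "relative"
    deff: float = 2.0
    mean_household_size: float = 5.0
    confidence_z: float = 1.96
    variance_model: VarianceModel = VarianceModel.poisson

    def __post_init__(self) -> None:
        if self.expected_cmr <= 0:
            raise ValueError("expected_cmr must be positive")
        if self.recall_days <= 0:
            raise ValueError("recall_days must be positive")
        if self.deff < 1:
            raise ValueError("deff must be >= 1")
        if self.mean_household_size <= 0:
            raise ValueError("mean_household_size must be positive")
        if self.precision <= 0:
            raise ZeroPrecisionError("precision must be positive")
        if self.precision_kind not in ("absolute", "relative"):
            raise ValueError("precision_kind must be 'absolute' or 'relative'")
        VarianceModel(self.variance_model)

    @property
    def period_risk(self) -> float:
        """p: per-person probability of death over the recall period."""
        return self.expected_cmr * self.recall_days / PER

    @property
    def period_precision(self) -> float:
        """d: the target half-width on the period-risk scale."""
        if self.precision_kind == "relative":
            return self.precision * self.period_risk
        return self.precision * self.recall_days / PER


@dataclass(frozen=True)
class SampleSizePlan:
    persons_required: float
    households_required: int
    n_clusters: Optional[int] = None
    households_per_cluster: Optional[int] = None

    @property
    def total_households(self) -> Optional[int]:
        if self.n_clusters is None or self.households_per_cluster is None:
            return None
        return self.n_clusters * self.households_per_cluster


def required_persons(spec: SurveyDesignSpec) -> float:
    """Unrounded persons required under the spec's variance model."""
    p = spec.period_risk
    d = spec.period_precision
    if d == 0:
        raise ZeroPrecisionError("precision resolves to zero on the risk scale")
    model = VarianceModel(spec.variance_model)
    if model is VarianceModel.binomial:
        if p >= 1:
            raise InvalidRiskError(f"period risk {p:.3f} >= 1 under binomial model")
        v = p * (1 - p)
    else:
        v = p
    return spec.deff * spec.confidence_z**2 * v / d**2


def round_households(households: float) -> int:
    """Truncate to a whole household (with a float-noise guard)."""
    return int(math.floor(households + 1e-9))


def required_households(
    spec: SurveyDesignSpec,
    households_per_cluster: Optional[int] = None,
) -> SampleSizePlan:
    """Sample-size plan: persons, households, and optional cluster layout."""
    persons = required_persons(spec)
    households = round_households(persons / spec.mean_household_size)
    n_clusters = None
    if households_per_cluster is not None:
        n_clusters, _ = cluster_allocation(households, households_per_cluster)
    return SampleSizePlan(persons, households, n_clusters, households_per_cluster)


def cluster_allocation(
    households: int,
    households_per_cluster: int,
    n_clusters_override: Optional[int] = None,
) -> tuple[int, int]:
    """Clusters needed to cover ``households``, and the resulting total.

    ``n_clusters_override`` accepts a stated design verbatim (published
    designs are sometimes internally inconsistent, e.g. "200 clusters of
    32 households (6402 households)"); with an override the total is the
    household requirement itself, not clusters x size.
    """
    if households <= 0 or households_per_cluster <= 0:
        raise ValueError("households and households_per_cluster must be positive")
    if n_clusters_override is not None:
        return n_clusters_override, households
    n_clusters = math.ceil(households / households_per_cluster)
    return n_clusters, n_clusters * households_per_cluster


def achievable_precision(spec: SurveyDesignSpec, persons: float) -> float:
    """Precision (deaths per 10,000 person-days) achievable with ``persons``.

    Inverse of :func:`required_persons`: d on the period scale solves
    n = DEFF z^2 V / d^2, converted back to the rate scale.  The
    ``precision`` field of ``spec`` is ignored.
    """
    if persons <= 0:
        raise ValueError("persons must be positive")
    p = spec.period_risk
    model = VarianceModel(spec.variance_model)
    v = p * (1 - p) if model is VarianceModel.binomial else p
    d = math.sqrt(spec.deff * spec.confidence_z**2 * v / persons)
    return d * PER / spec.recall_days
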