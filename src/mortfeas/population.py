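"""Rapid population-size estimation for mortality denominators.

Where no registration or surveillance denominator exists, field teams
estimate population size quickly by one of three designs:

* **structure counts x sampled occupancy** — count residential structures
  exhaustively, estimate mean occupants per structure from a small nested
  survey, multiply (optionally per stratum, summing strata);
* **quadrant density** — measure population in a sample of map quadrants,
  pool a density (persons/km^2), scale to the full area;
* **centric systematic area sampling (CSAS)** — partition the region into
  a square grid and select, for each cell mostly inside the region, the k
  villages nearest the cell centroid; a spatially spread, non-self-weighting
  village sample.

Coordinates are planar kilometres; sites are small enough that geodesy is
out of scope.  Selection is deterministic: distance ties break
lexicographically on village id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box

from shapely.geometry.base import BaseGeometry


class EmptySampleError(ValueError):
    """An estimator received an empty occupancy or quadrant sample."""


@dataclass(frozen=True)
class OccupancySample:
    occupants: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.occupants):
            raise ValueError("occupant counts must be >= 0")

    @property
    def structures_sampled(self) -> int:
        return len(self.occupants)

    @property
    def mean_occupancy(self) -> float:
        if not self.occupants:
            raise EmptySampleError("occupancy sample is empty")
        return float(np.mean(self.occupants))


@dataclass(frozen=True)
class StratumEstimate:
    stratum_id: str
    n_structures: int
    mean_occupancy: float

    @property
    def population(self) -> float:
        return self.n_structures * self.mean_occupancy


@dataclass(frozen=True, order=True)
class VillagePoint:
    village_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("village coordinates must be finite")


def estimate_population_structures(
    n_structures: int,
    sample: OccupancySample,
    stratum_id: str = "all",
) -> StratumEstimate:
    """Population = structure count x mean occupancy from the nested survey."""
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")
    return StratumEstimate(stratum_id, n_structures, sample.mean_occupancy)


def combine_strata(estimates: Sequence[StratumEstimate]) -> float:
    """Stratified total: simple sum of stratum populations."""
    return sum(e.population for e in estimates)


def bootstrap_population_ci(
    n_structures: int,
    sample: OccupancySample,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Nonparametric bootstrap interval over the occupancy sample.

    An extension for planning purposes; rapid field estimates are usually
    reported without uncertainty.
    """
    rng = rng or np.random.default_rng()
    occ = np.asarray(sample.occupants, dtype=float)
    if occ.size == 0:
        raise EmptySampleError("occupancy sample is empty")
    means = rng.choice(occ, size=(n_boot, occ.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means * n_structures, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def quadrant_density_estimate(
    sampled: Sequence[tuple[float, float]],
    total_area: float,
) -> float:
    """Scale pooled sampled density (persons/km^2) to the total area.

    ``sampled`` is a sequence of (quadrant_area_km2, quadrant_population)
    pairs; the pooled density is total sampled persons over total sampled
    area, so larger quadrants carry proportionally more weight.
    """
    sampled = list(sampled)
    area = sum(a for a, _ in sampled)
    if area <= 0:
        raise EmptySampleError("total sampled quadrant area must be positive")
    if any(a < 0 or p < 0 for a, p in sampled):
        raise ValueError("areas and populations must be >= 0")
    if total_area < area - 1e-9:
        raise ValueError("total_area must be >= sampled area")
    density = sum(p for _, p in sampled) / area
    return density * total_area


# ---------------------------------------------------------------------------
# centric systematic area sampling


def _as_region(region) -> BaseGeometry:
    if isinstance(region, BaseGeometry):
        return region
    if isinstance(region, (tuple, list)) and len(region) == 4:
        xmin, ymin, xmax, ymax = region
        return box(xmin, ymin, xmax, ymax)
    raise TypeError("region must be a shapely geometry or (xmin, ymin, xmax, ymax)")


def grid_cells(
    region,
    quadrat_size: float,
    min_coverage: float = 0.5,
) -> list[tuple[float, float]]:
    """Centroids of grid cells whose area falls mostly within the region.

    The grid is anchored at the region's lower-left bound.  A cell is kept
    iff the fraction of its area intersecting the region exceeds
    ``min_coverage`` (default: more than half inside).  Centroids are
    returned in row-major order (south to north, west to east).
    """
    if quadrat_size <= 0:
        raise ValueError("quadrat_size must be positive")
    geom = _as_region(region)
    xmin, ymin, xmax, ymax = geom.bounds
    nx = max(1, math.ceil((xmax - xmin) / quadrat_size - 1e-9))
    ny = max(1, math.ceil((ymax - ymin) / quadrat_size - 1e-9))
    cell_area = quadrat_size * quadrat_size
    centroids = []
    for j in range(ny):
        for i in range(nx):
            cell = box(
                xmin + i * quadrat_size,
                ymin + j * quadrat_size,
                xmin + (i + 1) * quadrat_size,
                ymin + (j + 1) * quadrat_size,
            )
            if cell.intersection(geom).area / cell_area > min_coverage:
                centroids.append(
                    (xmin + (i + 0.5) * quadrat_size, ymin + (j + 0.5) * quadrat_size)
                )
    return centroids


def csas_select(
    villages: Sequence[VillagePoint],
    region,
    quadrat_size: float,
    k: int = 3,
    min_coverage: float = 0.5,
    restrict_to_region: bool = True,
) -> dict[tuple[float, float], list[VillagePoint]]:
    """Select the k villages nearest each qualifying quadrat centroid.

    Villages are selected at most once: cells are processed in row-major
    order and already-selected villages are unavailable to later cells.
    Distance is planar Euclidean; exact ties break on village_id.  Cells
    with no remaining villages select fewer than k (possibly none).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    geom = _as_region(region)
    if restrict_to_region:
        candidates = [v for v in villages if geom.intersects(Point(v.x, v.y))]
    else:
        candidates = list(villages)
    ids = {v.village_id for v in candidates}
    if len(ids) != len(candidates):
        raise ValueError("village ids must be unique")

    selection: dict[tuple[float, float], list[VillagePoint]] = {}
    available = set(candidates)
    for cx, cy in grid_cells(geom, quadrat_size, min_coverage):
        ranked = sorted(
            available,
            key=lambda v: (math.hypot(v.x - cx, v.y - cy), v.village_id),
        )
        chosen = ranked[:k]
        selection[(cx, cy)] = chosen
        available -= set(chosen)
    return selection


def selected_villages(
    selection: dict[tuple[float, float], list[VillagePoint]]
) -> list[VillagePoint]:
    """Flatten a CSAS selection, preserving cell order."""
    out: list[VillagePoint] = []
    for cell in selection:
        out.extend(selection[cell])
    return out
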