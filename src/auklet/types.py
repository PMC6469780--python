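"""Shared domain types and enumerations for the vulnerability pipeline.

The pipeline compares two decadal periods of weekly gridded ocean-projection
fields (a recent baseline and a future window) for a small ensemble of model
realizations, and scores change per polygonal assessment unit in units of the
baseline spatial standard deviation.

All geometry lives in the grid's projected plane with kilometre coordinates;
cell (0, 0) sits at the origin corner and cell centers are at
``origin + (index + 0.5) * cell_size_km`` (row-major, 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

# ---------------------------------------------------------------------------
# Enumerations / variable metadata
# ---------------------------------------------------------------------------

#: Decadal comparison windows (calendar-year inclusive ranges).
PERIODS: dict[str, tuple[int, int]] = {
    "recent": (2003, 2012),
    "future": (2030, 2039),
}

#: Month sets defining the meteorological seasons used for slice selection.
SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
}

SEASONS = ("winter", "spring", "summer", "fall")
GUILDS = ("petrels", "seaducks", "alcids", "gulls/terns")

#: Depth classes: shallow/deep aggregate water-column layers; surface and
#: bottom are single-level variables with no vertical resolution.
DEPTH_CLASSES: dict[str, Optional[tuple[float, float]]] = {
    "shallow": (0.0, 60.0),
    "deep": (75.0, 200.0),
    "surface": None,
    "bottom": None,
}


@dataclass(frozen=True)
class VariableInfo:
    """Static metadata for one assessed ocean variable."""

    units: str
    #: "layered" (full water column), "surface" or "bottom" (single level).
    vertical: str
    #: +1 when an *increase* is adverse (warming), -1 when a decrease is.
    adverse_sign: int
    #: physical clamp applied by the synthetic generator, (lo, hi) or None
    bounds: Optional[tuple[float, float]]
    #: True for prey variables matched through the foraging table
    is_forage: bool


VARIABLES: dict[str, VariableInfo] = {
    "swt": VariableInfo("degC", "layered", +1, None, False),
    "sea_ice": VariableInfo("% ice fraction area", "surface", -1, (0.0, 100.0), False),
    "large_copepods": VariableInfo("mg C/m^3", "layered", -1, (0.0, np.inf), True),
    "euphausiids": VariableInfo("mg C/m^3", "layered", -1, (0.0, np.inf), True),
    "benthic_infauna": VariableInfo("mg C/m^2", "bottom", -1, (0.0, np.inf), True),
}

PREY_CATEGORIES = ("large_copepods", "euphausiids", "benthic_infauna")
#: forage column recorded for completeness but never assessable
UNASSESSED_PREY = "fish_cephalopods_unassessed"


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

#: Default vertical layering: ten layers spanning 0-200 m.  Six layers tile
#: the shallow class exactly, three the deep class; the 60-75 m layer belongs
#: to neither class.
DEFAULT_DEPTH_BOUNDS: tuple[float, ...] = (
    0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 75.0, 100.0, 150.0, 200.0,
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the assessment raster (projected plane, km)."""

    nx: int
    ny: int
    cell_size_km: float = 10.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    depth_layer_bounds: tuple[float, ...] = DEFAULT_DEPTH_BOUNDS

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell in each direction")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        bounds = np.asarray(self.depth_layer_bounds, dtype=float)
        if bounds.ndim != 1 or bounds.size < 2 or np.any(np.diff(bounds) <= 0):
            raise ValueError("depth_layer_bounds must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return len(self.depth_layer_bounds) - 1

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km ** 2

    @property
    def layer_intervals(self) -> list[tuple[float, float]]:
        b = self.depth_layer_bounds
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates, returned as (x of columns, y of rows)."""
        xs = self.origin_x + (np.arange(self.nx) + 0.5) * self.cell_size_km
        ys = self.origin_y + (np.arange(self.ny) + 0.5) * self.cell_size_km
        return xs, ys

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in projected km."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.nx * self.cell_size_km,
            self.origin_y + self.ny * self.cell_size_km,
        )


# ---------------------------------------------------------------------------
# Gridded data containers
# ---------------------------------------------------------------------------


@dataclass
class GridField:
    """One variable's space-time(-depth) values for one model realization.

    ``values`` is 4-D (time, depth, y, x); single-level variables carry a
    depth axis of length one with ``depth_bounds`` None.  Missing cells are
    NaN, exposed alongside a boolean mask by :meth:`mask`.
    """

    variable: str
    model: str
    units: str
    times: np.ndarray  # datetime64 array, ordered
    depth_bounds: Optional[tuple[tuple[float, float], ...]]
    values: np.ndarray  # (time, depth, y, x), NaN = missing
    spec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (time, depth, y, x)")
        nt, nz, ny, nx = self.values.shape
        if nt != self.times.size:
            raise ValueError("time axis length mismatch")
        if (ny, nx) != (self.spec.ny, self.spec.nx):
            raise ValueError("spatial shape does not match grid spec")
        if self.depth_bounds is not None and nz != len(self.depth_bounds):
            raise ValueError("depth axis length mismatch")
        if np.any(np.diff(self.times.astype("int64")) <= 0):
            raise ValueError("time axis must be strictly increasing")
        validate_variable_values(self.variable, self.units, self.values)

    def mask(self) -> np.ndarray:
        """Boolean missing-value mask (True = missing)."""
        return np.isnan(self.values)


@dataclass
class PeriodMeanField:
    """Per-cell decadal mean for one (variable, model, period, season).

    ``depth_class`` is one of shallow/deep/surface/bottom once the vertical
    axis has been collapsed; while still per-layer it is None and
    ``depth_bounds`` records the layer interval.
    """

    variable: str
    model: str
    period: str
    season: str
    depth_class: Optional[str]
    values: np.ndarray  # (y, x), NaN = missing
    n_slices: int
    spec: GridSpec
    depth_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.ny, self.spec.nx):
            raise ValueError("values shape does not match grid spec")
        if self.n_slices <= 0:
            raise ValueError("n_slices must be positive")

    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


def validate_variable_values(variable: str, units: str, values: np.ndarray) -> None:
    """Check units and physical bounds for a variable; raise ValueError."""
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable id: {variable!r}")
    info = VARIABLES[variable]
    if units != info.units:
        raise ValueError(
            f"unit mismatch for {variable!r}: expected {info.units!r}, got {units!r}"
        )
    if info.bounds is not None:
        lo, hi = info.bounds
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(
                f"{variable} values outside physical bounds [{lo}, {hi}]"
            )


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

REGION_KINDS = ("study_area", "lme", "ecoregion", "core_area")


@dataclass
class Region:
    """Named polygon in grid-projected coordinates."""

    id: str
    kind: str
    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind: {self.kind!r}")
        if self.geometry.is_empty:
            raise ValueError(f"region {self.id!r}: empty geometry")
        if not self.geometry.is_valid:
            raise ValueError(f"region {self.id!r}: invalid (self-intersecting) geometry")


@dataclass
class CoreArea(Region):
    """Single-species core area polygon with occupancy attributes."""

    species: str = ""
    guild: str = ""
    occupancy_season: str = ""
    iba_id: str = ""
    area_km2: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.guild not in GUILDS:
            raise ValueError(f"core area {self.id!r}: unknown guild {self.guild!r}")
        if self.occupancy_season not in SEASONS:
            raise ValueError(
                f"core area {self.id!r}: unknown season {self.occupancy_season!r}"
            )
        if self.area_km2 <= 0:
            raise ValueError(f"core area {self.id!r}: area_km2 must be positive")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.geometry.centroid
        return (c.x, c.y)


# ---------------------------------------------------------------------------
# Foraging matrix
# ---------------------------------------------------------------------------

FORAGE_LEVELS = ("none", "secondary", "primary")


@dataclass
class ForagingMatrix:
    """Species-by-prey table with entries none / secondary / primary.

    Fish and cephalopods are recorded for completeness but never generate an
    assessment; species with no assessable prey at all are excluded from the
    analysis (solely piscivorous species).
    """

    entries: dict[str, dict[str, str]]  # species -> prey category -> level

    def __post_init__(self) -> None:
        for sp, row in self.entries.items():
            for cat, level in row.items():
                if cat not in PREY_CATEGORIES + (UNASSESSED_PREY,):
                    raise ValueError(f"{sp}: unknown prey category {cat!r}")
                if level not in FORAGE_LEVELS:
                    raise ValueError(f"{sp}: unknown forage level {level!r}")

    @property
    def species(self) -> list[str]:
        return list(self.entries)

    def assessable_prey(self, species: str) -> list[str]:
        """Prey variables (in canonical order) marked for ``species``."""
        if species not in self.entries:
            raise KeyError(f"species not in foraging matrix: {species!r}")
        row = self.entries[species]
        return [c for c in PREY_CATEGORIES if row.get(c, "none") != "none"]

    def is_excluded(self, species: str) -> bool:
        """True when the species has no assessable prey (fish-only diet)."""
        return not self.assessable_prey(species)


# ---------------------------------------------------------------------------
# Scoring results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Vulnerability cut points on the adverse-direction SD-change scale."""

    moderate_abs: float = 0.1
    high_abs: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.moderate_abs < self.high_abs):
            raise ValueError("require 0 < moderate_abs < high_abs")


#: variable -> sign whose product with the SD change gives "adverse" change
DEFAULT_DIRECTIONS: dict[str, int] = {
    v: info.adverse_sign for v, info in VARIABLES.items()
}

CATEGORIES = ("low", "moderate", "high")


@dataclass
class SDChangeResult:
    """SD-change statistic and category for one (unit, variable, model)."""

    unit_id: str
    variable: str
    model: str
    season: str
    depth_class: Optional[str]
    mu_t1: float
    mu_t2: float
    sd_ref: float
    sd_change: float
    category: str


@dataclass
class VulnerabilitySummary:
    """Cross-model roll-up for one unit × variable."""

    unit_id: str
    variable: str
    season: str
    depth_class: Optional[str]
    per_model: dict[str, SDChangeResult]
    agreement_count: int
    magnitude: float
    ma_score: float
    ma_category: str

    @property
    def vulnerable_any_model(self) -> bool:
        return self.agreement_count >= 1


@dataclass
class GroupMetrics:
    """Group-level (LME / ecoregion / species-set) vulnerability metrics."""

    group_id: str
    variable: str
    n_tested: int
    pct_vulnerable: float
    agreement_fraction: float
    magnitude: float
    ma_score: float


@dataclass
class CoreAreaAssessment:
    """Full per-core-area result across all matched variables."""

    core_area: CoreArea
    lme_id: str
    ecoregion_id: Optional[str]
    summaries: list[VulnerabilitySummary]
    all_variables_vulnerable: bool

    def summary_for(self, variable: str, depth_class: Optional[str] = None
                    ) -> Optional[VulnerabilitySummary]:
        for s in self.summaries:
            if s.variable == variable and (depth_class is None
                                           or s.depth_class == depth_class):
                return s
        return None
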