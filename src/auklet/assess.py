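"""Per-core-area assessment orchestration and summary tables.

Ties the stages together for each single-species core area: minimum-area and
data-cell filtering, majority-overlap assignment to Large Marine Ecosystems
and ecoregions, matching forage variables through the species foraging table
and the occupancy season, extraction of cell values from the core area's
minimum bounding rectangle, scoring against the nearest-cells moving window,
and the species-count / group-metric summary tables.

Conventions: seawater temperature is assessed annually (shallow always, deep
when the area overlaps deep-water data cells); sea ice with spring data and
only for areas inside the maximum-ice-extent mask; forage variables at the
core area's occupancy season.  Solely piscivorous species are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy

from .aggregate import clip_to_ice_extent, combine_depth, period_mean, single_level_mean
from .scoring import (
    group_metrics,
    moving_window_sd,
    region_sd,
    score_unit,
    sd_change,
    summarize_models,
)
from .synthetic import DEFAULT_MODELS
from .types import (
    GUILDS,
    CoreArea,
    CoreAreaAssessment,
    ForagingMatrix,
    GridField,
    GridSpec,
    GroupMetrics,
    PeriodMeanField,
    Region,
    Thresholds,
    VARIABLES,
    VulnerabilitySummary,
)

logger = logging.getLogger("auklet")

__all__ = [
    "AssessmentConfig", "filter_core_areas", "assign_lme",
    "extract_cell_values", "variables_for_species", "assess_all",
    "summarize_species_counts", "fraction_all_variable_vulnerable",
    "group_metrics_table", "region_change_table", "results_table",
]


@dataclass
class AssessmentConfig:
    """Knobs of the per-core-area assessment."""

    min_area_km2: float = 300.0
    min_cells_per_depth: int = 3
    models: tuple[str, ...] = DEFAULT_MODELS
    thresholds: Thresholds = dc_field(default_factory=Thresholds)
    window_k: int = 2500

    def __post_init__(self) -> None:
        if self.min_cells_per_depth < 1:
            raise ValueError("min_cells_per_depth must be >= 1")
        if not self.models:
            raise ValueError("models must be non-empty")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _cells_in_bounding_rect(spec: GridSpec, area: CoreArea) -> np.ndarray:
    """Boolean (y, x) mask of cells whose centers fall inside the area's
    axis-aligned minimum bounding rectangle (closed edges)."""
    minx, miny, maxx, maxy = area.geometry.bounds
    xs, ys = spec.cell_centers()
    in_x = (xs >= minx) & (xs <= maxx)
    in_y = (ys >= miny) & (ys <= maxy)
    return np.outer(in_y, in_x)


def extract_cell_values(field: PeriodMeanField, core_area: CoreArea
                        ) -> np.ndarray:
    """Non-missing cell values inside the core area's bounding rectangle.

    The rectangle rule deliberately includes cells outside the polygon
    itself (e.g. the notch of an L-shaped area).
    """
    rect = _cells_in_bounding_rect(field.spec, core_area)
    vals = field.values[rect & ~field.mask()]
    if vals.size == 0:
        raise ValueError(
            f"core area {core_area.id!r}: no non-missing cells in its "
            f"bounding rectangle for {field.variable}/{field.model}")
    return vals


def assign_lme(core_area: CoreArea, lmes: Sequence[Region]) -> str:
    """Id of the LME with the largest intersected area (ties: smallest id)."""
    best: tuple[float, str] | None = None
    for lme in lmes:
        a = core_area.geometry.intersection(lme.geometry).area
        if a > 0 and (best is None or a > best[0]
                      or (a == best[0] and lme.id < best[1])):
            best = (a, lme.id)
    if best is None:
        raise ValueError(
            f"core area {core_area.id!r} overlaps no reference region")
    return best[1]


# ---------------------------------------------------------------------------
# Variable matching and filtering
# ---------------------------------------------------------------------------


def variables_for_species(species: str, matrix: ForagingMatrix,
                          core_area: CoreArea, *,
                          in_ice_zone: bool = False
                          ) -> list[tuple[str, str]]:
    """(variable, season) pairs to assess for a species' core area.

    Forage variables from the foraging table pair with the occupancy season;
    seawater temperature always pairs with "annual"; sea ice pairs with
    "spring" and only inside the ice zone.  Fish-only species return an
    empty forage list (and only physical variables).
    """
    if species not in matrix.entries:
        raise KeyError(f"species not in foraging matrix: {species!r}")
    pairs: list[tuple[str, str]] = [("swt", "annual")]
    if in_ice_zone:
        pairs.append(("sea_ice", "spring"))
    forage = matrix.assessable_prey(species)
    if not forage:
        logger.info("species %s has no assessable forage variables "
                    "(fish-only diet)", species)
    pairs.extend((v, core_area.occupancy_season) for v in forage)
    return pairs


def _depth_class_masks(cache: "_MeanCache", config: AssessmentConfig
                       ) -> dict[str, np.ndarray]:
    """Recent-period data-cell masks per depth class (non-missing in every
    model, so availability does not depend on model ordering)."""
    masks: dict[str, np.ndarray] = {}
    for cls, variable, season in (("shallow", "swt", "annual"),
                                  ("deep", "swt", "annual"),
                                  ("surface", "sea_ice", "spring"),
                                  ("bottom", "benthic_infauna", None)):
        if variable not in cache.variables:
            continue
        season = season or cache.any_season(variable)
        if season is None:
            continue
        per_model = [~cache.get(variable, m, season, cls, "recent").mask()
                     for m in config.models]
        masks[cls] = np.logical_and.reduce(per_model)
    return masks


def filter_core_areas(areas: Sequence[CoreArea], grid: GridSpec,
                      config: AssessmentConfig, *,
                      class_masks: Optional[Mapping[str, np.ndarray]] = None,
                      forage_classes: Optional[Mapping[str, set[str]]] = None,
                      ) -> list[CoreArea]:
    """Retain areas above the minimum extent with enough data cells.

    An area passes when its extent exceeds ``min_area_km2`` and, for every
    depth class *available* to it (>= 1 data cell in its bounding
    rectangle among the classes its variables use), at least
    ``min_cells_per_depth`` data cells are present.  Without data masks only
    the area criterion applies.
    """
    kept: list[CoreArea] = []
    for area in areas:
        if not area.area_km2 > config.min_area_km2:
            logger.info("dropping %s: area %.0f km2 <= %.0f km2",
                        area.id, area.area_km2, config.min_area_km2)
            continue
        if class_masks:
            rect = _cells_in_bounding_rect(grid, area)
            uses = {"shallow", "deep", "surface"}
            if forage_classes is not None:
                uses = {"shallow", "deep", "surface"} & set(class_masks)
                species_classes = forage_classes.get(area.species, set())
                uses |= species_classes & set(class_masks)
            short = []
            for cls in sorted(uses & set(class_masks)):
                n = int((class_masks[cls] & rect).sum())
                if 0 < n < config.min_cells_per_depth:
                    short.append((cls, n))
            if short:
                logger.info("dropping %s: too few data cells %s", area.id, short)
                continue
        kept.append(area)
    if not kept:
        logger.warning("no core areas retained after filtering")
    return kept


# ---------------------------------------------------------------------------
# Period-mean cache
# ---------------------------------------------------------------------------


class _MeanCache:
    """Lazily computed period means per (variable, model, season, class)."""

    def __init__(self, fields: Mapping[tuple[str, str], GridField],
                 ice_mask: Optional[np.ndarray]):
        self.fields = dict(fields)
        self.ice_mask = ice_mask
        self._cache: dict[tuple, PeriodMeanField] = {}
        self.variables = sorted({v for (v, _) in self.fields})
        self._seasons_seen: dict[str, str] = {}

    def any_season(self, variable: str) -> Optional[str]:
        return self._seasons_seen.get(variable, "annual")

    def get(self, variable: str, model: str, season: str, depth_class: str,
            period: str) -> PeriodMeanField:
        key = (variable, model, season, depth_class, period)
        if key in self._cache:
            return self._cache[key]
        if (variable, model) not in self.fields:
            raise ValueError(
                f"missing input field for variable={variable!r} model={model!r}")
        gridfield = self.fields[(variable, model)]
        if VARIABLES[variable].vertical == "layered":
            layers = period_mean(gridfield, period, season)
            pmf = combine_depth(layers, depth_class)
        else:
            pmf = single_level_mean(gridfield, period, season)
        if variable == "sea_ice":
            if self.ice_mask is None:
                raise ValueError("sea_ice assessment requires an ice-extent mask")
            pmf = clip_to_ice_extent(pmf, self.ice_mask)
        self._seasons_seen[variable] = season
        self._cache[key] = pmf
        return pmf


def _expand_depth_classes(variable: str, season: str,
                          class_masks: Mapping[str, np.ndarray],
                          rect: np.ndarray, config: AssessmentConfig
                          ) -> list[str]:
    """Depth classes at which to assess a (variable, season) for one area."""
    vertical = VARIABLES[variable].vertical
    if vertical == "surface":
        return ["surface"]
    if vertical == "bottom":
        return ["bottom"]
    if variable == "swt":
        classes = ["shallow"]
        deep_mask = class_masks.get("deep")
        if deep_mask is not None and \
                int((deep_mask & rect).sum()) >= config.min_cells_per_depth:
            classes.append("deep")
        return classes
    return ["shallow"]  # zooplankton variables are shallow-water only


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def assess_all(fields: Mapping[tuple[str, str], GridField],
               areas: Sequence[CoreArea], matrix: ForagingMatrix,
               config: AssessmentConfig, *,
               lmes: Sequence[Region],
               ecoregions: Sequence[Region] = (),
               ice_mask: Optional[np.ndarray] = None,
               ) -> list[CoreAreaAssessment]:
    """Run the full per-core-area assessment; deterministic given inputs.

    ``fields`` maps (variable, model) to weekly grids covering both periods.
    Missing (variable, model) combinations required by the matched variables
    raise before any scoring; every retained area yields a summary for every
    matched (variable, season, depth class) or the run fails loudly.
    """
    if not areas:
        raise ValueError("no core areas supplied")
    spec = areas[0].geometry  # placeholder; real spec from any field
    if not fields:
        raise ValueError("no input fields supplied")
    spec = next(iter(fields.values())).spec

    # up-front closure check: every needed (variable, model) must be present
    needed_vars = {"swt"}
    if ice_mask is not None and "sea_ice" in {v for v, _ in fields}:
        needed_vars.add("sea_ice")
    for area in areas:
        if area.species in matrix.entries:
            needed_vars.update(matrix.assessable_prey(area.species))
    missing = [(v, m) for v in sorted(needed_vars) for m in config.models
               if (v, m) not in fields]
    if missing:
        raise ValueError(f"missing model/variable input fields: {missing}")

    cache = _MeanCache(fields, ice_mask)
    # touch forage seasons so the cache can answer availability queries
    forage_classes: dict[str, set[str]] = {}
    for area in areas:
        if area.species not in matrix.entries:
            raise KeyError(f"species not in foraging matrix: {area.species!r}")
        classes = set()
        for v in matrix.assessable_prey(area.species):
            classes.add("bottom" if VARIABLES[v].vertical == "bottom" else "shallow")
        forage_classes[area.species] = classes

    class_masks = _depth_class_masks(cache, config)
    retained = filter_core_areas(areas, spec, config, class_masks=class_masks,
                                 forage_classes=forage_classes)

    assessments: list[CoreAreaAssessment] = []
    for area in retained:
        if matrix.is_excluded(area.species):
            logger.info("excluding %s: species %s has no assessable prey",
                        area.id, area.species)
            continue
        rect = _cells_in_bounding_rect(spec, area)
        ice_zone = False
        if "surface" in class_masks:
            ice_zone = int((class_masks["surface"] & rect).sum()) >= 1
        pairs = variables_for_species(area.species, matrix, area,
                                      in_ice_zone=ice_zone)
        lme_id = assign_lme(area, lmes)
        eco_id = assign_lme(area, ecoregions) if ecoregions else None
        summaries: list[VulnerabilitySummary] = []
        for variable, season in pairs:
            for depth_class in _expand_depth_classes(
                    variable, season, class_masks, rect, config):
                per_model = []
                for model in config.models:
                    recent = cache.get(variable, model, season, depth_class, "recent")
                    future = cache.get(variable, model, season, depth_class, "future")
                    mu1 = float(np.mean(extract_cell_values(recent, area)))
                    mu2 = float(np.mean(extract_cell_values(future, area)))
                    sd_ref = moving_window_sd(recent, area.centroid,
                                              k=config.window_k)
                    per_model.append(score_unit(
                        area.id, variable, model, season, depth_class,
                        mu1, mu2, sd_ref, thresholds=config.thresholds))
                summaries.append(summarize_models(
                    per_model, thresholds=config.thresholds))
        assessments.append(CoreAreaAssessment(
            core_area=area, lme_id=lme_id, ecoregion_id=eco_id,
            summaries=summaries,
            all_variables_vulnerable=bool(summaries) and all(
                s.ma_category in ("moderate", "high") for s in summaries)))
    return assessments


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------


def summarize_species_counts(assessments: Sequence[CoreAreaAssessment],
                             variable: str,
                             depth_class: Optional[str] = None
                             ) -> pd.DataFrame:
    """Per-species moderate/high counts per model and for the M-A score.

    Mirrors the published species-count tables: one row per species with its
    guild, "moderate, high" counts under each model and under the
    magnitude-agreement classification, the number of core areas assessed
    for the variable, and a totals row equal to the column sums.
    """
    if not assessments:
        raise ValueError("no assessments supplied")
    models = sorted({m for a in assessments for s in a.summaries
                     for m in s.per_model})
    rows = []
    for guild in GUILDS:
        species = sorted({a.core_area.species for a in assessments
                          if a.core_area.guild == guild})
        for sp in species:
            summaries = [
                s for a in assessments if a.core_area.species == sp
                for s in [a.summary_for(variable, depth_class)] if s is not None
            ]
            if not summaries:
                continue
            row: dict[str, object] = {"guild": guild, "species": sp}
            for m in models:
                cats = [s.per_model[m].category for s in summaries]
                row[f"{m}_moderate"] = sum(c == "moderate" for c in cats)
                row[f"{m}_high"] = sum(c == "high" for c in cats)
            row["ma_moderate"] = sum(s.ma_category == "moderate" for s in summaries)
            row["ma_high"] = sum(s.ma_category == "high" for s in summaries)
            row["total_core_areas"] = len(summaries)
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = (["guild", "species"]
                + [f"{m}_{c}" for m in models for c in ("moderate", "high")]
                + ["ma_moderate", "ma_high", "total_core_areas"])
        return pd.DataFrame(columns=cols)
    totals = df.drop(columns=["guild", "species"]).sum()
    totals["guild"], totals["species"] = "", "Total"
    return pd.concat([df, totals.to_frame().T[df.columns]], ignore_index=True)


def fraction_all_variable_vulnerable(
        assessments: Sequence[CoreAreaAssessment]) -> int:
    """Whole-percent share of core areas vulnerable for every assessed
    variable (magnitude-agreement category moderate or high)."""
    if not assessments:
        raise ValueError("no assessments supplied")
    n_vuln = sum(a.all_variables_vulnerable for a in assessments)
    return round(100.0 * n_vuln / len(assessments))


def group_metrics_table(assessments: Sequence[CoreAreaAssessment],
                        group_by: str = "lme") -> pd.DataFrame:
    """Group-level metrics per (group, variable, depth class).

    ``group_by`` is "lme" or "ecoregion".  One row per combination with the
    number of areas tested, percent vulnerable under >= 1 model, agreement
    fraction, magnitude, and magnitude-agreement score.
    """
    if group_by not in ("lme", "ecoregion"):
        raise ValueError("group_by must be 'lme' or 'ecoregion'")
    key = (lambda a: a.lme_id) if group_by == "lme" else (lambda a: a.ecoregion_id)
    combos = sorted({(key(a), s.variable, s.depth_class or "")
                     for a in assessments for s in a.summaries})
    rows = []
    for group_id, variable, depth_class in combos:
        summaries = [s for a in assessments if key(a) == group_id
                     for s in a.summaries
                     if s.variable == variable
                     and (s.depth_class or "") == depth_class]
        gm = group_metrics(summaries, group_id, variable)
        rows.append({
            "group": group_id, "variable": variable, "depth_class": depth_class,
            "n_tested": gm.n_tested, "pct_vulnerable": gm.pct_vulnerable,
            "agreement_fraction": gm.agreement_fraction,
            "magnitude": gm.magnitude, "ma_score": gm.ma_score,
        })
    return pd.DataFrame(rows)


def results_table(assessments: Sequence[CoreAreaAssessment]) -> pd.DataFrame:
    """Tidy per-(area, variable, depth class, model) results table.

    One row per model result plus a "3-model" summary row carrying the
    magnitude, agreement count and magnitude-agreement score.
    """
    rows = []
    for a in assessments:
        base = {"core_area": a.core_area.id, "species": a.core_area.species,
                "guild": a.core_area.guild, "lme": a.lme_id,
                "ecoregion": a.ecoregion_id or ""}
        for s in a.summaries:
            for model in sorted(s.per_model):
                r = s.per_model[model]
                rows.append({**base, "variable": s.variable,
                             "depth_class": s.depth_class or "",
                             "season": s.season, "model": model,
                             "mu_t1": r.mu_t1, "mu_t2": r.mu_t2,
                             "sd_ref": r.sd_ref, "sd_change": r.sd_change,
                             "category": r.category,
                             "agreement_count": "", "ma_score": ""})
            rows.append({**base, "variable": s.variable,
                         "depth_class": s.depth_class or "",
                         "season": s.season, "model": "3-model",
                         "mu_t1": "", "mu_t2": "", "sd_ref": "",
                         "sd_change": s.magnitude, "category": s.ma_category,
                         "agreement_count": s.agreement_count,
                         "ma_score": s.ma_score})
    return pd.DataFrame(rows)


def region_change_table(fields: Mapping[tuple[str, str], GridField],
                        regions: Sequence[Region], models: Sequence[str],
                        *, ice_mask: Optional[np.ndarray] = None,
                        season_policy: Optional[Mapping[str, str]] = None
                        ) -> pd.DataFrame:
    """Region-scale change summary (reference-region scoring).

    For each (region, variable, depth class): the recent mean and spatial SD
    across region cells, the model-average projected change, and the SD
    change value normalized by the region's own recent SD — the region-scale
    analogue of the core-area scoring, using the region polygon itself as
    the reference.
    """
    season_policy = dict(season_policy or {})
    cache = _MeanCache(fields, ice_mask)
    variables = sorted({v for (v, _) in fields})
    rows = []
    for region in regions:
        for variable in variables:
            vertical = VARIABLES[variable].vertical
            classes = (["shallow", "deep"] if variable == "swt"
                       else ["shallow"] if vertical == "layered"
                       else [vertical])
            season = season_policy.get(
                variable, "spring" if variable == "sea_ice" else "annual")
            for depth_class in classes:
                mu1s, mu2s, sds = [], [], []
                skip = False
                for model in models:
                    recent = cache.get(variable, model, season, depth_class,
                                       "recent")
                    future = cache.get(variable, model, season, depth_class,
                                       "future")
                    xs, ys = recent.spec.cell_centers()
                    gx, gy = np.meshgrid(xs, ys)
                    inside = contains_xy(region.geometry, gx.ravel(),
                                         gy.ravel()).reshape(gx.shape)
                    ok = inside & ~recent.mask()
                    if ok.sum() < 2:
                        skip = True
                        break
                    mu1s.append(float(np.mean(recent.values[ok])))
                    mu2s.append(float(np.mean(future.values[inside & ~future.mask()])))
                    sds.append(region_sd(recent, region))
                if skip:
                    continue
                mu1, mu2 = float(np.mean(mu1s)), float(np.mean(mu2s))
                sd1 = float(np.mean(sds))
                rows.append({
                    "region": region.id, "variable": variable,
                    "depth_class": depth_class, "season": season,
                    "recent_mean": mu1, "recent_sd": sd1,
                    "projected_change": mu2 - mu1,
                    "sd_change": sd_change(mu1, mu2, sd1) if sd1 > 0 else np.nan,
                })
    return pd.DataFrame(rows)
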