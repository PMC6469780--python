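"""Synthetic projection ensembles with known ground truth.

Generates pseudo-model gridded ocean fields, region and core-area polygons,
an ice-extent mask and a foraging matrix that together emulate the
statistical structure the vulnerability analysis assumes: weekly slices over
two decadal periods, spatially correlated baseline fields, divergent
per-model trends injected in units of the baseline spatial SD, and a mix of
core areas on both sides of the minimum-area filter.

The generated fields are statistical stand-ins — no ocean dynamics, real
geography, or realistic bathymetry is attempted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon, box

from .types import (
    GUILDS,
    PERIODS,
    PREY_CATEGORIES,
    SEASONS,
    UNASSESSED_PREY,
    VARIABLES,
    CoreArea,
    ForagingMatrix,
    GridField,
    GridSpec,
    Region,
)

__all__ = [
    "ManifestEntry",
    "TruthManifest",
    "default_manifest",
    "weekly_times",
    "simulate_model_fields",
    "generate_regions",
    "generate_ice_mask",
    "generate_core_areas",
    "generate_foraging_matrix",
    "DEFAULT_MODELS",
    "DEFAULT_SPECIES_GUILDS",
]

DEFAULT_MODELS = ("mod_a", "mod_b", "mod_c")


def _tag(s: str) -> int:
    """Stable 32-bit tag for a string, for seed derivation."""
    return zlib.crc32(s.encode("utf-8"))


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    """Ground-truth generation parameters for one (variable, model).

    ``injected_change_sd`` is the intended future-minus-recent shift in units
    of the recent spatial SD; the generator applies it grid-wide so the
    whole-grid SD-change estimate recovers it directly.
    """

    variable: str
    model: str
    injected_change_sd: float
    baseline_mean: float
    spatial_sd: float
    temporal_noise_sd: float
    spatial_correlation_length_km: float
    seed: int
    seasonal_amplitude: float = 0.0
    region: str = "study_area"


@dataclass
class TruthManifest:
    """Collection of ground-truth entries, keyed by (variable, model)."""

    entries: dict[tuple[str, str], ManifestEntry] = field(default_factory=dict)

    def add(self, entry: ManifestEntry) -> None:
        self.entries[(entry.variable, entry.model)] = entry

    def get(self, variable: str, model: str) -> ManifestEntry:
        key = (variable, model)
        if key not in self.entries:
            raise KeyError(f"no manifest entry for variable={variable!r} model={model!r}")
        return self.entries[key]

    @property
    def models(self) -> list[str]:
        return sorted({m for (_, m) in self.entries})

    @property
    def variables(self) -> list[str]:
        return sorted({v for (v, _) in self.entries})


#: Per-model injected changes (units of baseline spatial SD) emulating a
#: small ensemble with divergent trends: consistent warming and ice loss,
#: weak and inconsistent forage trends.
_DEFAULT_INJECTIONS: dict[str, tuple[float, float, float]] = {
    "swt": (0.28, 0.33, 0.09),
    "sea_ice": (-0.65, -0.50, -0.20),
    "large_copepods": (0.06, 0.07, 0.13),
    "euphausiids": (0.02, 0.03, 0.10),
    "benthic_infauna": (0.10, -0.02, 0.02),
}

#: (baseline mean, spatial SD) per variable, in the variable's units; chosen
#: away from the physical clamp bounds so clamping stays inactive by default.
_DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "swt": (4.0, 1.2),
    "sea_ice": (50.0, 12.0),
    "large_copepods": (0.45, 0.12),
    "euphausiids": (2.3, 0.5),
    "benthic_infauna": (2500.0, 800.0),
}


def default_manifest(seed: int = 0,
                     models: tuple[str, ...] = DEFAULT_MODELS) -> TruthManifest:
    """Manifest emulating the study conditions: 3 models, 5 variables.

    Temporal noise defaults to 10% of the spatial SD and the spatial
    correlation length to 50 km (five cells at the default resolution).
    """
    manifest = TruthManifest()
    for variable, injections in _DEFAULT_INJECTIONS.items():
        mean, sd = _DEFAULT_BASELINES[variable]
        for model, inj in zip(models, injections):
            manifest.add(ManifestEntry(
                variable=variable,
                model=model,
                injected_change_sd=inj,
                baseline_mean=mean,
                spatial_sd=sd,
                temporal_noise_sd=0.1 * sd,
                spatial_correlation_length_km=50.0,
                seed=(seed * 1_000_003 + _tag(variable + "/" + model)) % (2**31),
            ))
    return manifest


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------


def weekly_times(period: str) -> np.ndarray:
    """52 weekly timestamps per year across the period's calendar years."""
    if period not in PERIODS:
        raise ValueError(f"unknown period id: {period!r}")
    y0, y1 = PERIODS[period]
    times = []
    for year in range(y0, y1 + 1):
        start = np.datetime64(f"{year}-01-04")
        times.append(start + np.arange(52) * np.timedelta64(7, "D"))
    return np.concatenate(times).astype("datetime64[ns]")


def _baseline_field(entry: ManifestEntry, spec: GridSpec) -> np.ndarray:
    """Spatially correlated baseline with exact mean and population SD.

    Gaussian-kernel smoothing of white noise, then an exact affine
    standardization so the whole-grid spatial SD equals ``spatial_sd``; this
    keeps downstream parameter recovery closed-form.
    """
    if entry.spatial_sd == 0:
        return np.full((spec.ny, spec.nx), entry.baseline_mean, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(
        [entry.seed, _tag(entry.variable), _tag(entry.model), 101]))
    white = rng.standard_normal((spec.ny, spec.nx))
    sigma = entry.spatial_correlation_length_km / spec.cell_size_km
    smooth = gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = smooth.std()  # population divisor
    if sd == 0:  # pathological (1x1 grid); fall back to constant
        return np.full((spec.ny, spec.nx), entry.baseline_mean, dtype=float)
    return entry.baseline_mean + (smooth - smooth.mean()) / sd * entry.spatial_sd


def simulate_model_fields(spec: GridSpec, variable: str, model: str,
                          period: str, manifest: TruthManifest,
                          seed: int) -> GridField:
    """Simulate one (variable, model, period) of weekly gridded slices.

    The per-cell long-run mean is the shared baseline field, plus the
    injected shift (in units of the spatial SD) for the future period.  Noise
    is i.i.d. per slice and cell; physical clamps (ice in [0, 100], biomass
    >= 0) are applied after adding noise.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable id: {variable!r}")
    if period not in PERIODS:
        raise ValueError(f"unknown period id: {period!r}")
    entry = manifest.get(variable, model)
    if entry.spatial_sd < 0:
        raise ValueError("spatial_sd must be non-negative")
    if entry.temporal_noise_sd < 0:
        raise ValueError("temporal_noise_sd must be non-negative")

    info = VARIABLES[variable]
    times = weekly_times(period)
    nt = times.size
    nz = spec.n_layers if info.vertical == "layered" else 1
    depth_bounds = tuple(spec.layer_intervals) if info.vertical == "layered" else None

    base = _baseline_field(entry, spec)
    if period == "future":
        base = base + entry.injected_change_sd * entry.spatial_sd

    values = np.broadcast_to(base, (nt, nz, spec.ny, spec.nx)).copy()

    if entry.seasonal_amplitude != 0.0:
        doy = ((times - times.astype("datetime64[Y]").astype(times.dtype))
               / np.timedelta64(1, "D")).astype(float)
        cycle = entry.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
        values += cycle[:, None, None, None]

    if entry.temporal_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed), entry.seed, _tag(variable), _tag(model), _tag(period), 202]))
        values += rng.normal(0.0, entry.temporal_noise_sd, size=values.shape)

    if info.bounds is not None:  # clamp after noise so bounds hold in output
        lo, hi = info.bounds
        np.clip(values, lo, None if np.isinf(hi) else hi, out=values)

    return GridField(
        variable=variable, model=model, units=info.units, times=times,
        depth_bounds=depth_bounds, values=values, spec=spec,
    )


# ---------------------------------------------------------------------------
# Regions, ice mask, core areas
# ---------------------------------------------------------------------------


def generate_regions(spec: GridSpec) -> list[Region]:
    """Study area, two LMEs (west/east halves) and four ecoregion quadrants."""
    x0, y0, x1, y1 = spec.extent
    xm, ym = (x0 + x1) / 2, (y0 + y1) / 2
    regions = [
        Region("study_area", "study_area", "Study Area", box(x0, y0, x1, y1)),
        Region("lme_east", "lme", "Eastern LME", box(xm, y0, x1, y1)),
        Region("lme_west", "lme", "Western LME", box(x0, y0, xm, y1)),
        Region("eco_ne", "ecoregion", "Northeast", box(xm, ym, x1, y1)),
        Region("eco_nw", "ecoregion", "Northwest", box(x0, ym, xm, y1)),
        Region("eco_se", "ecoregion", "Southeast", box(xm, y0, x1, ym)),
        Region("eco_sw", "ecoregion", "Southwest", box(x0, y0, xm, ym)),
    ]
    return regions


def generate_ice_mask(spec: GridSpec) -> np.ndarray:
    """Boolean maximum-ice-extent mask: the northern half of the grid."""
    mask = np.zeros((spec.ny, spec.nx), dtype=bool)
    mask[spec.ny // 2:, :] = True
    return mask


#: species -> (guild, diet archetype); diet archetypes drive the foraging
#: matrix: "plankton" = both zooplankton, "benthos" = benthic infauna,
#: "mixed" = euphausiids primary + copepods secondary, "fish_only" = excluded
DEFAULT_SPECIES_GUILDS: dict[str, tuple[str, str]] = {
    "northern_fulmar": ("petrels", "mixed"),
    "fork_tailed_storm_petrel": ("petrels", "plankton"),
    "steller_eider": ("seaducks", "benthos"),
    "black_scoter": ("seaducks", "benthos"),
    "crested_auklet": ("alcids", "plankton"),
    "least_auklet": ("alcids", "plankton"),
    "pigeon_guillemot": ("alcids", "benthos"),
    "tufted_puffin": ("alcids", "fish_only"),
    "black_legged_kittiwake": ("gulls/terns", "mixed"),
    "glaucous_winged_gull": ("gulls/terns", "mixed"),
}


def generate_core_areas(spec: GridSpec, n: int, species_pool: list[str],
                        seed: int) -> list[CoreArea]:
    """Place ``n`` rectangular/elliptical core areas within the grid extent.

    Target areas are drawn on both sides of the 300 km^2 minimum-area filter
    so downstream filtering is exercised; species cycle through the pool and
    occupancy seasons cycle through winter/spring/summer/fall, so every
    season appears once n >= 4.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = [s for s in species_pool if s not in DEFAULT_SPECIES_GUILDS]
    if unknown:
        raise ValueError(f"species without guild mapping: {unknown}")
    x0, y0, x1, y1 = spec.extent
    max_dim = min(x1 - x0, y1 - y0)
    # need room for the largest polygon the sampler can request
    a_hi = min(2500.0, (0.8 * max_dim) ** 2)
    a_lo = min(120.0, a_hi / 4)
    if a_hi < 4 * spec.cell_area_km2:
        raise ValueError(
            f"grid extent too small to place non-degenerate core areas "
            f"({max_dim:.0f} km across)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    areas: list[CoreArea] = []
    for i in range(n):
        # alternate below/above the filter threshold
        if i % 2 == 0:
            target = float(rng.uniform(max(320.0, a_lo), a_hi))
        else:
            target = float(rng.uniform(a_lo, min(295.0, a_hi)))
        aspect = float(rng.uniform(0.6, 1.6))
        w = min(np.sqrt(target * aspect), 0.8 * (x1 - x0))
        h = min(target / w, 0.8 * (y1 - y0))
        elliptical = i % 3 == 2  # every third area elliptical
        # ellipse semi-axes chosen so the ellipse area equals w*h
        mx = w / np.sqrt(np.pi) if elliptical else w / 2
        my = h / np.sqrt(np.pi) if elliptical else h / 2
        cx = float(rng.uniform(x0 + mx, x1 - mx))
        cy = float(rng.uniform(y0 + my, y1 - my))
        if elliptical:
            circle = Point(0.0, 0.0).buffer(1.0, quad_segs=16)
            xs, ys = np.asarray(circle.exterior.xy[0]), np.asarray(circle.exterior.xy[1])
            geom = Polygon(np.column_stack([cx + xs * mx, cy + ys * my]))
        else:
            geom = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        species = species_pool[i % len(species_pool)]
        guild, _ = DEFAULT_SPECIES_GUILDS[species]
        areas.append(CoreArea(
            id=f"ca_{i:03d}",
            kind="core_area",
            name=f"Core area {i}",
            geometry=geom,
            species=species,
            guild=guild,
            occupancy_season=SEASONS[i % 4],
            iba_id=f"iba_{i // 2:03d}",
            area_km2=float(geom.area),
        ))
    return areas


# ---------------------------------------------------------------------------
# Foraging matrix
# ---------------------------------------------------------------------------


def generate_foraging_matrix(species_pool: list[str]) -> ForagingMatrix:
    """Species-by-prey table from each species' diet archetype.

    Seaducks and other benthos feeders mark benthic infauna only;
    planktivores mark both zooplankton categories; mixed feeders mark
    euphausiids as primary and copepods as secondary alongside fish; fish-only
    species mark nothing assessable and are excluded downstream.
    """
    if not species_pool:
        raise ValueError("species_pool must be non-empty")
    entries: dict[str, dict[str, str]] = {}
    for sp in species_pool:
        if sp not in DEFAULT_SPECIES_GUILDS:
            raise ValueError(f"species without guild mapping: {sp!r}")
        _, diet = DEFAULT_SPECIES_GUILDS[sp]
        row = {c: "none" for c in PREY_CATEGORIES}
        row[UNASSESSED_PREY] = "none"
        if diet == "plankton":
            row["large_copepods"] = "primary"
            row["euphausiids"] = "primary"
        elif diet == "benthos":
            row["benthic_infauna"] = "primary"
        elif diet == "mixed":
            row["euphausiids"] = "primary"
            row["large_copepods"] = "secondary"
            row[UNASSESSED_PREY] = "primary"
        elif diet == "fish_only":
            row[UNASSESSED_PREY] = "primary"
        else:  # pragma: no cover
            raise ValueError(f"unknown diet archetype {diet!r}")
        entries[sp] = row
    return ForagingMatrix(entries)
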