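"""Readers and writers for the pipeline's standard formats.

Gridded fields travel as NetCDF-convention files (dimensions time, depth, y,
x; CF time encoding; NaN missing values), regions as GeoJSON feature
collections in grid-projected kilometre coordinates, and the foraging matrix,
truth manifest and results tables as UTF-8 CSV with a header row.  Every
writer is paired with a reader and the pair round-trips losslessly up to
floating-point representation; readers validate all type invariants on load
and raise ``ValueError`` naming the defect.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .synthetic import ManifestEntry, TruthManifest
from .types import (
    CoreArea,
    ForagingMatrix,
    GridField,
    GridSpec,
    PREY_CATEGORIES,
    Region,
    UNASSESSED_PREY,
    VARIABLES,
)

__all__ = [
    "read_grid", "write_grid",
    "read_regions", "write_regions",
    "read_foraging_table", "write_foraging_table",
    "read_manifest", "write_manifest",
    "read_ice_mask", "write_ice_mask",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Gridded fields (NetCDF)
# ---------------------------------------------------------------------------


def write_grid(field: GridField, path: PathLike) -> Path:
    """Write a :class:`GridField` to a NetCDF file; returns the path."""
    path = Path(path)
    spec = field.spec
    xs, ys = spec.cell_centers()
    nz = field.values.shape[1]
    coords = {
        "time": field.times,
        "depth": np.arange(nz, dtype=np.int32),
        "y": ys,
        "x": xs,
    }
    data_vars = {
        field.variable: (("time", "depth", "y", "x"),
                         field.values.astype(np.float32)),
    }
    if field.depth_bounds is not None:
        tops = np.array([b[0] for b in field.depth_bounds])
        bots = np.array([b[1] for b in field.depth_bounds])
        data_vars["depth_top"] = (("depth",), tops)
        data_vars["depth_bottom"] = (("depth",), bots)
    ds = xr.Dataset(data_vars, coords=coords, attrs={
        "variable": field.variable,
        "model": field.model,
        "units": field.units,
        "cell_size_km": spec.cell_size_km,
        "origin_x": spec.origin_x,
        "origin_y": spec.origin_y,
        "depth_layer_bounds": json.dumps(list(spec.depth_layer_bounds)),
        "has_depth_axis": int(field.depth_bounds is not None),
    })
    ds[field.variable].attrs["units"] = field.units
    ds.to_netcdf(path, engine="scipy")
    return path


def read_grid(path: PathLike) -> GridField:
    """Read a NetCDF grid file written by :func:`write_grid`."""
    path = Path(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for dim in ("time", "depth", "y", "x"):
        if dim not in ds.dims:
            raise ValueError(f"{path.name}: missing dimension {dim!r}")
    variable = str(ds.attrs.get("variable", ""))
    if variable not in VARIABLES:
        raise ValueError(f"{path.name}: unknown variable id {variable!r}")
    info = VARIABLES[variable]
    units = str(ds.attrs.get("units", ""))
    if units != info.units:
        raise ValueError(
            f"{path.name}: unit mismatch for {variable!r}: "
            f"expected {info.units!r}, got {units!r}")
    times = ds["time"].values
    if np.any(np.diff(times.astype("int64")) <= 0):
        raise ValueError(f"{path.name}: non-monotone time axis")
    has_depth = bool(ds.attrs.get("has_depth_axis", 0))
    if info.vertical == "layered" and not has_depth:
        raise ValueError(f"{path.name}: depth axis required for {variable!r}")
    if info.vertical != "layered" and has_depth:
        raise ValueError(
            f"{path.name}: {variable!r} is {info.vertical}-only but a depth "
            f"axis is present")
    depth_bounds = None
    if has_depth:
        tops = ds["depth_top"].values
        bots = ds["depth_bottom"].values
        depth_bounds = tuple((float(t), float(b)) for t, b in zip(tops, bots))
    spec = GridSpec(
        nx=ds.sizes["x"], ny=ds.sizes["y"],
        cell_size_km=float(ds.attrs["cell_size_km"]),
        origin_x=float(ds.attrs["origin_x"]),
        origin_y=float(ds.attrs["origin_y"]),
        depth_layer_bounds=tuple(json.loads(ds.attrs["depth_layer_bounds"])),
    )
    values = ds[variable].values.astype(float)
    # GridField.__post_init__ re-validates bounds, shapes and monotonicity
    return GridField(variable=variable, model=str(ds.attrs.get("model", "")),
                     units=units, times=times, depth_bounds=depth_bounds,
                     values=values, spec=spec)


# ---------------------------------------------------------------------------
# Regions (GeoJSON)
# ---------------------------------------------------------------------------


def write_regions(regions: Sequence[Region], path: PathLike) -> Path:
    """Write regions/core areas as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = []
    for r in regions:
        props = {"id": r.id, "kind": r.kind, "name": r.name}
        if isinstance(r, CoreArea):
            props.update(species=r.species, guild=r.guild,
                         season=r.occupancy_season, iba_id=r.iba_id,
                         area_km2=r.area_km2)
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(r.geometry)})
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
    return path


def read_regions(path: PathLike) -> list[Region]:
    """Read a GeoJSON FeatureCollection of regions and core areas.

    Features with ``kind == "core_area"`` come back as :class:`CoreArea`;
    invalid geometry or unknown guild/season tokens raise ``ValueError``.
    """
    path = Path(path)
    gj = json.loads(path.read_text())
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path.name}: not a GeoJSON FeatureCollection")
    out: list[Region] = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {}) or {}
        geom = shape(feat["geometry"])
        kind = props.get("kind", "")
        common = dict(id=str(props.get("id", "")), kind=kind,
                      name=str(props.get("name", "")), geometry=geom)
        try:
            if kind == "core_area":
                out.append(CoreArea(
                    **common,
                    species=str(props.get("species", "")),
                    guild=str(props.get("guild", "")),
                    occupancy_season=str(props.get("season", "")),
                    iba_id=str(props.get("iba_id", "")),
                    area_km2=float(props.get("area_km2", geom.area)),
                ))
            else:
                out.append(Region(**common))
        except ValueError as exc:
            raise ValueError(f"{path.name}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Foraging matrix (CSV)
# ---------------------------------------------------------------------------

_FORAGE_COLUMNS = ("species",) + PREY_CATEGORIES + (UNASSESSED_PREY,)


def write_foraging_table(matrix: ForagingMatrix, path: PathLike) -> Path:
    rows = []
    for sp, row in matrix.entries.items():
        rows.append({"species": sp, **{c: row.get(c, "none")
                                       for c in _FORAGE_COLUMNS[1:]}})
    pd.DataFrame(rows, columns=list(_FORAGE_COLUMNS)).to_csv(path, index=False)
    return Path(path)


def read_foraging_table(path: PathLike) -> ForagingMatrix:
    """Read the species-by-prey CSV; duplicate species rows are an error."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("none")
    missing = [c for c in _FORAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path.name}: duplicated species rows: {sorted(set(dupes))}")
    entries = {
        row["species"]: {c: row[c] for c in _FORAGE_COLUMNS[1:]}
        for _, row in df.iterrows()
    }
    try:
        return ForagingMatrix(entries)
    except ValueError as exc:
        raise ValueError(f"{path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# Truth manifest (CSV)
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = (
    "region", "variable", "model", "injected_change_sd", "baseline_mean",
    "spatial_sd", "temporal_noise_sd", "spatial_correlation_length_km",
    "seasonal_amplitude", "seed",
)


def write_manifest(manifest: TruthManifest, path: PathLike) -> Path:
    rows = []
    for (variable, model) in sorted(manifest.entries):
        e = manifest.entries[(variable, model)]
        rows.append({c: getattr(e, c) for c in _MANIFEST_COLUMNS})
    # default float formatting (repr) round-trips exactly in Python 3
    pd.DataFrame(rows, columns=list(_MANIFEST_COLUMNS)).to_csv(path, index=False)
    return Path(path)


def read_manifest(path: PathLike) -> TruthManifest:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    manifest = TruthManifest()
    for _, row in df.iterrows():
        manifest.add(ManifestEntry(
            region=str(row["region"]),
            variable=str(row["variable"]),
            model=str(row["model"]),
            injected_change_sd=float(row["injected_change_sd"]),
            baseline_mean=float(row["baseline_mean"]),
            spatial_sd=float(row["spatial_sd"]),
            temporal_noise_sd=float(row["temporal_noise_sd"]),
            spatial_correlation_length_km=float(row["spatial_correlation_length_km"]),
            seasonal_amplitude=float(row["seasonal_amplitude"]),
            seed=int(row["seed"]),
        ))
    return manifest


# ---------------------------------------------------------------------------
# Ice-extent mask (CSV of 0/1)
# ---------------------------------------------------------------------------


def write_ice_mask(mask: np.ndarray, path: PathLike) -> Path:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter=",")
    return Path(path)


def read_ice_mask(path: PathLike) -> np.ndarray:
    arr = np.loadtxt(path, dtype=int, delimiter=",", ndmin=2)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{Path(path).name}: mask entries must be 0 or 1")
    return arr.astype(bool)
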