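"""Temporal and vertical aggregation of weekly gridded slices.

Weekly slices collapse to per-cell decadal means by season (winter = Dec-Feb,
spring = Mar-May, summer = Jun-Aug, fall = Sep-Nov; "annual" keeps every
slice), per depth layer.  Layer means then combine into the two water-column
depth classes by thickness weighting: shallow covers layers contained in
0-60 m, deep those contained in 75-200 m; a layer straddling the 60-75 m gap
belongs to neither class.  Sea-ice fields are additionally clipped to a
maximum-ice-extent mask.

All means use equal slice weights and skip missing (NaN) cells; a cell is
missing in the output only where every contributing slice/layer is missing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DEPTH_CLASSES,
    PERIODS,
    SEASON_MONTHS,
    GridField,
    PeriodMeanField,
    VARIABLES,
)

__all__ = ["period_mean", "combine_depth", "clip_to_ice_extent",
           "single_level_mean", "season_of_months"]


def season_of_months(months: np.ndarray) -> np.ndarray:
    """Season label per calendar month (vectorized)."""
    out = np.empty(months.shape, dtype=object)
    for season, mm in SEASON_MONTHS.items():
        out[np.isin(months, mm)] = season
    return out


def _slice_selector(field: GridField, period: str, season: str) -> np.ndarray:
    if period not in PERIODS:
        raise ValueError(f"unknown period id: {period!r}")
    if season != "annual" and season not in SEASON_MONTHS:
        raise ValueError(f"unknown season id: {season!r}")
    idx = pd.DatetimeIndex(field.times)
    y0, y1 = PERIODS[period]
    sel = (idx.year >= y0) & (idx.year <= y1)
    if season != "annual":
        sel &= np.isin(idx.month, SEASON_MONTHS[season])
    if not sel.any():
        raise ValueError(
            f"no time slices fall in period={period!r} season={season!r}")
    return np.asarray(sel)


def _nanmean_time(values: np.ndarray) -> np.ndarray:
    """Mean over axis 0 ignoring NaN; all-NaN cells stay NaN (no warning)."""
    count = np.sum(~np.isnan(values), axis=0)
    total = np.nansum(values, axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


def period_mean(field: GridField, period: str, season: str
                ) -> list[PeriodMeanField]:
    """Per-cell mean over the period/season window, one result per layer.

    ``season="annual"`` averages every slice in the period.  Returns a list
    of per-layer :class:`PeriodMeanField` (single-element for surface- or
    bottom-only variables) with ``depth_class`` still unset.
    """
    sel = _slice_selector(field, period, season)
    n_slices = int(sel.sum())
    sub = field.values[sel]  # (n, z, y, x)
    means = _nanmean_time(sub)
    out = []
    nz = means.shape[0]
    for iz in range(nz):
        bounds = field.depth_bounds[iz] if field.depth_bounds is not None else None
        out.append(PeriodMeanField(
            variable=field.variable, model=field.model, period=period,
            season=season, depth_class=None, values=means[iz],
            n_slices=n_slices, spec=field.spec, depth_bounds=bounds))
    return out


def combine_depth(layers: Sequence[PeriodMeanField], depth_class: str
                  ) -> PeriodMeanField:
    """Thickness-weighted mean of the layers contained in a depth class.

    A layer contributes iff its interval lies within the class window; per
    cell, weights renormalize over the layers that are non-missing there, so
    the effective weights always sum to one.
    """
    if depth_class not in ("shallow", "deep"):
        raise ValueError(f"depth class must be shallow or deep, got {depth_class!r}")
    if not layers:
        raise ValueError("no layers supplied")
    first = layers[0]
    if VARIABLES[first.variable].vertical != "layered":
        raise ValueError(
            f"{first.variable!r} has no water-column depth axis; "
            f"cannot combine into {depth_class!r}")
    lo, hi = DEPTH_CLASSES[depth_class]
    chosen = [pmf for pmf in layers
              if pmf.depth_bounds is not None
              and pmf.depth_bounds[0] >= lo and pmf.depth_bounds[1] <= hi]
    if not chosen:
        raise ValueError(
            f"no depth layer lies within the {depth_class} window [{lo}, {hi}] m")
    stack = np.stack([pmf.values for pmf in chosen])          # (k, y, x)
    weights = np.array([pmf.depth_bounds[1] - pmf.depth_bounds[0]
                        for pmf in chosen])[:, None, None]
    valid = ~np.isnan(stack)
    wsum = np.sum(weights * valid, axis=0)
    total = np.nansum(np.where(valid, stack * weights, 0.0), axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(wsum > 0, total / np.maximum(wsum, 1e-300), np.nan)
    return PeriodMeanField(
        variable=first.variable, model=first.model, period=first.period,
        season=first.season, depth_class=depth_class, values=values,
        n_slices=first.n_slices, spec=first.spec,
        depth_bounds=(lo, hi))


def single_level_mean(field: GridField, period: str, season: str
                      ) -> PeriodMeanField:
    """Period mean for a surface- or bottom-only variable, class attached."""
    info = VARIABLES[field.variable]
    if info.vertical == "layered":
        raise ValueError(f"{field.variable!r} is a layered variable")
    (pmf,) = period_mean(field, period, season)
    pmf.depth_class = info.vertical  # "surface" or "bottom"
    return pmf


def clip_to_ice_extent(field: PeriodMeanField, mask: np.ndarray
                       ) -> PeriodMeanField:
    """Set cells outside the maximum-ice-extent mask to missing."""
    if field.variable != "sea_ice":
        raise ValueError("ice-extent clipping applies to sea_ice only")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {field.values.shape}")
    values = np.where(mask, field.values, np.nan)
    return PeriodMeanField(
        variable=field.variable, model=field.model, period=field.period,
        season=field.season, depth_class=field.depth_class, values=values,
        n_slices=field.n_slices, spec=field.spec,
        depth_bounds=field.depth_bounds)
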