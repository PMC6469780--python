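"""The normalized-change statistic and its vulnerability roll-ups.

The core statistic is the SD change value

    sd_change = (mu_t2 - mu_t1) / SD_t1

the future-minus-recent mean change normalized by the recent-period spatial
standard deviation of a reference region (or of the nearest-k-cells moving
window around a core-area centroid).  Values are classified against fixed
thresholds on the adverse-direction scale: a change of about 0.1 SD in the
adverse direction marks moderate vulnerability (the prey-decline change
point of Cury et al.'s "one-third for the birds"), and 1 SD or more marks
high vulnerability.  Decreases are adverse for sea ice and the forage
variables; increases are adverse for seawater temperature.

Cross-model roll-ups: *agreement* counts models classifying a unit as
moderately or highly vulnerable; *magnitude* is the mean SD change across
models; the *magnitude-agreement score* is magnitude times the agreement
fraction.  All spatial SDs use the population divisor (n).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from shapely import contains_xy

from .types import (
    CATEGORIES,
    DEFAULT_DIRECTIONS,
    GroupMetrics,
    PeriodMeanField,
    Region,
    SDChangeResult,
    Thresholds,
    VulnerabilitySummary,
)

__all__ = [
    "sd_change", "region_sd", "moving_window_sd", "classify_vulnerability",
    "summarize_models", "group_metrics", "score_unit",
]


def sd_change(mu_t1: float, mu_t2: float, sd_ref: float) -> float:
    """(mu_t2 - mu_t1) / sd_ref; requires a positive reference SD."""
    if not sd_ref > 0:
        raise ValueError(
            f"degenerate reference region: sd_ref must be > 0, got {sd_ref}")
    return (mu_t2 - mu_t1) / sd_ref


def region_sd(field: PeriodMeanField, region: Region) -> float:
    """Population SD of the non-missing cell means inside a region polygon.

    Cell membership is by cell center falling inside the polygon.
    """
    xs, ys = field.spec.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    inside = contains_xy(region.geometry, gx.ravel(), gy.ravel()).reshape(gx.shape)
    vals = field.values[inside & ~field.mask()]
    if vals.size < 2:
        raise ValueError(
            f"region {region.id!r}: need >= 2 non-missing cells, got {vals.size}")
    return float(np.std(vals))  # population divisor


def moving_window_sd(field: PeriodMeanField, centroid: tuple[float, float],
                     k: int = 2500) -> float:
    """Population SD over the k non-missing cells nearest a centroid.

    Distance is Euclidean from cell center to the centroid; ties break
    lexicographically by (distance, row, col) so the window is deterministic
    across platforms.  With fewer than k data cells the window saturates and
    the result equals the all-data-cell SD.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    xs, ys = field.spec.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    valid = ~field.mask()
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError(f"need >= 2 non-missing cells, got {n_valid}")
    rows, cols = np.nonzero(valid)
    dx = gx[valid] - centroid[0]
    dy = gy[valid] - centroid[1]
    dist = np.hypot(dx, dy)
    order = np.lexsort((cols, rows, dist))  # primary key last: distance
    take = order[: min(k, n_valid)]
    return float(np.std(field.values[valid][take]))


def classify_vulnerability(value: float, variable: str,
                           thresholds: Thresholds = Thresholds(),
                           direction: Optional[Mapping[str, int]] = None) -> str:
    """Map an SD-change value to low / moderate / high vulnerability.

    The value is flipped onto the adverse-direction scale first (positive =
    adverse): increases are adverse for seawater temperature, decreases for
    everything else.  Categories partition the reals: adverse < moderate
    cut -> low; < high cut -> moderate; otherwise high.
    """
    if not np.isfinite(value):
        raise ValueError(f"SD-change value must be finite, got {value}")
    direction = DEFAULT_DIRECTIONS if direction is None else direction
    if variable not in direction:
        raise ValueError(f"no adverse direction defined for {variable!r}")
    adverse = direction[variable] * value
    if adverse < thresholds.moderate_abs:
        return "low"
    if adverse < thresholds.high_abs:
        return "moderate"
    return "high"


def score_unit(unit_id: str, variable: str, model: str, season: str,
               depth_class: Optional[str], mu_t1: float, mu_t2: float,
               sd_ref: float, thresholds: Thresholds = Thresholds(),
               direction: Optional[Mapping[str, int]] = None) -> SDChangeResult:
    """Convenience constructor: compute sd_change and classify in one step."""
    value = sd_change(mu_t1, mu_t2, sd_ref)
    return SDChangeResult(
        unit_id=unit_id, variable=variable, model=model, season=season,
        depth_class=depth_class, mu_t1=mu_t1, mu_t2=mu_t2, sd_ref=sd_ref,
        sd_change=value,
        category=classify_vulnerability(value, variable, thresholds, direction))


def summarize_models(results: Sequence[SDChangeResult],
                     thresholds: Thresholds = Thresholds(),
                     direction: Optional[Mapping[str, int]] = None
                     ) -> VulnerabilitySummary:
    """Cross-model summary for one unit × variable.

    Requires exactly one result per model (duplicates or an empty list are
    errors).  Magnitude is the mean SD change; the magnitude-agreement score
    multiplies it by the fraction of models calling the unit vulnerable, and
    is itself classified on the same thresholds.
    """
    if not results:
        raise ValueError("no model results supplied")
    first = results[0]
    models = [r.model for r in results]
    if len(set(models)) != len(models):
        raise ValueError(f"duplicate model results: {sorted(models)}")
    for r in results[1:]:
        if (r.unit_id, r.variable, r.season, r.depth_class) != (
                first.unit_id, first.variable, first.season, first.depth_class):
            raise ValueError("results mix units/variables/seasons")
    n_models = len(results)
    agreement = sum(r.category in ("moderate", "high") for r in results)
    magnitude = float(np.mean([r.sd_change for r in results]))
    ma_score = magnitude * (agreement / n_models)
    return VulnerabilitySummary(
        unit_id=first.unit_id, variable=first.variable, season=first.season,
        depth_class=first.depth_class,
        per_model={r.model: r for r in results},
        agreement_count=agreement, magnitude=magnitude, ma_score=ma_score,
        ma_category=classify_vulnerability(
            ma_score, first.variable, thresholds, direction))


def group_metrics(summaries: Sequence[VulnerabilitySummary], group_id: str,
                  variable: str) -> GroupMetrics:
    """Aggregate unit summaries into group-level vulnerability metrics.

    ``pct_vulnerable`` is the share of units vulnerable under at least one
    model; ``agreement_fraction`` sums per-unit agreement counts over the
    total possible (units × models); the group magnitude-agreement score is
    the group magnitude times the agreement fraction.
    """
    if not summaries:
        raise ValueError(f"no summaries for group {group_id!r}")
    if any(s.variable != variable for s in summaries):
        raise ValueError("summaries mix variables")
    n = len(summaries)
    n_models = max(len(s.per_model) for s in summaries)
    pct = 100.0 * sum(s.vulnerable_any_model for s in summaries) / n
    agreement = sum(s.agreement_count for s in summaries) / (n_models * n)
    magnitude = float(np.mean([s.magnitude for s in summaries]))
    return GroupMetrics(
        group_id=group_id, variable=variable, n_tested=n,
        pct_vulnerable=pct, agreement_fraction=agreement,
        magnitude=magnitude, ma_score=magnitude * agreement)
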