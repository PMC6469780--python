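"""Shared fixtures: small grids, noise-free manifests, simulated ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from auklet import (
    DEFAULT_MODELS,
    GridSpec,
    ManifestEntry,
    TruthManifest,
    simulate_model_fields,
)
from auklet.types import VARIABLES


@pytest.fixture
def spec16() -> GridSpec:
    return GridSpec(nx=16, ny=16)


@pytest.fixture
def spec30() -> GridSpec:
    return GridSpec(nx=30, ny=30)


def make_manifest(injections: dict[str, dict[str, float]] | dict[str, float],
                  *, noise_frac: float = 0.0, seed: int = 7,
                  models: tuple[str, ...] = DEFAULT_MODELS) -> TruthManifest:
    """Manifest with chosen per-(variable, model) injected changes.

    ``injections`` maps variable -> injected change (same for all models) or
    variable -> {model: injected change}.  Baselines sit away from physical
    bounds; temporal noise is ``noise_frac`` of the spatial SD.
    """
    baselines = {
        "swt": (4.0, 1.2),
        "sea_ice": (50.0, 12.0),
        "large_copepods": (0.45, 0.12),
        "euphausiids": (2.3, 0.5),
        "benthic_infauna": (2500.0, 800.0),
    }
    manifest = TruthManifest()
    for variable, inj in injections.items():
        mean, sd = baselines[variable]
        for i, model in enumerate(models):
            k = inj[model] if isinstance(inj, dict) else inj
            manifest.add(ManifestEntry(
                variable=variable, model=model, injected_change_sd=float(k),
                baseline_mean=mean, spatial_sd=sd,
                temporal_noise_sd=noise_frac * sd,
                spatial_correlation_length_km=40.0,
                seed=seed * 100 + i))
    return manifest


def make_fields(spec: GridSpec, manifest: TruthManifest, seed: int = 11):
    """Simulate both periods for every (variable, model) in the manifest."""
    fields = {}
    for (variable, model) in manifest.entries:
        for period in ("recent", "future"):
            fld = simulate_model_fields(spec, variable, model, period,
                                        manifest, seed=seed)
            if period == "recent":
                fields[(variable, model)] = fld
            else:
                # store both periods in one GridField by concatenating times
                recent = fields[(variable, model)]
                fields[(variable, model)] = type(recent)(
                    variable=variable, model=model, units=recent.units,
                    times=np.concatenate([recent.times, fld.times]),
                    depth_bounds=recent.depth_bounds,
                    values=np.concatenate([recent.values, fld.values]),
                    spec=spec)
    return fields
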