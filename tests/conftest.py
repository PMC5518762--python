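import warnings

import numpy as np
import pandas as pd
import pytest

from hybridrange import BinaryMap, ClimateStack, run_study


def make_flat_stack(
    n: int = 10,
    resolution: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    layers: dict | None = None,
    mask: np.ndarray | None = None,
) -> ClimateStack:
    """All-land (unless masked) single- or multi-layer test grid."""
    west, south = origin
    if layers is None:
        layers = {"TEMP": np.full((n, n), 20.0)}
    if mask is None:
        mask = np.ones((n, n), dtype=bool)
    return ClimateStack(
        layers={k: np.asarray(v, dtype=float) for k, v in layers.items()},
        extent=(west, west + n * resolution, south, south + n * resolution),
        resolution=resolution,
        land_mask=mask,
    )


@pytest.fixture
def unit_stack() -> ClimateStack:
    """10x10 grid, 1-degree cells, extent [0,10]x[0,10], all land."""
    return make_flat_stack(10)


def truth_binary(suit_map, cutoff: float = 0.5) -> BinaryMap:
    """Binarise a truth suitability map at the conventional 0.5 contour."""
    v = suit_map.values
    return BinaryMap(np.where(np.isnan(v), np.nan, (v >= cutoff).astype(float)))


@pytest.fixture(scope="session")
def default_run():
    """The full default synthetic study (100x100 world, 24 species,
    300 occurrences per species, all scenarios), run once per session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(seed=1)
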