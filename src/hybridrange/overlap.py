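"""Pairwise geographic range overlap between garden plants and congeners.

Overlap of two binary consensus maps is scored two ways: by the TSS of one
map "predicting" the other over the unmasked land universe, and by the raw
count of cells suitable to both. The TSS orientation treats the congener
map as the reference by default (a configuration choice; the symmetrised
mean of both orientations is available for sensitivity runs — note TSS
overlap is not symmetric because the margins differ even though the
numerator ad-bc is). Pair metrics are averaged per garden plant over all
its congeners, separately per scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BinaryMap, DomainError
from .sdm import tss

logger = logging.getLogger(__name__)

ORIENTATIONS = ("congener_ref", "garden_ref", "symmetric")


def _land_values(a: BinaryMap, b: BinaryMap) -> tuple[np.ndarray, np.ndarray]:
    if a.values.shape != b.values.shape:
        raise DomainError("overlap maps live on different grids")
    mask_a = np.isnan(a.values)
    if not np.array_equal(mask_a, np.isnan(b.values)):
        raise DomainError("overlap maps have different no-data masks")
    return a.values[~mask_a] > 0, b.values[~mask_a] > 0


def range_size(bmap: BinaryMap) -> int:
    """Number of suitable unmasked cells."""
    return int(np.nansum(bmap.values))


def overlap_cells(garden: BinaryMap, congener: BinaryMap) -> int:
    """Count of unmasked cells suitable to both species (symmetric)."""
    g, c = _land_values(garden, congener)
    return int((g & c).sum())


def overlap_confusion(garden: BinaryMap, congener: BinaryMap) -> tuple[int, int, int, int]:
    """Confusion counts (a, b, c, d) with the congener map as reference:
    a both suitable, b garden-only, c congener-only, d neither."""
    g, c = _land_values(garden, congener)
    a = int((g & c).sum())
    b = int((g & ~c).sum())
    cc = int((~g & c).sum())
    d = int((~g & ~c).sum())
    return a, b, cc, d


def overlap_tss(
    garden: BinaryMap, congener: BinaryMap, orientation: str = "congener_ref"
) -> float:
    """TSS-scored range agreement between a garden plant and a congener.

    Raises :class:`DomainError` when a confusion margin is empty (a map
    that is all-suitable or all-unsuitable over land); callers exclude and
    log such pairs.
    """
    if orientation not in ORIENTATIONS:
        raise DomainError(f"unknown orientation {orientation!r}")
    a, b, c, d = overlap_confusion(garden, congener)
    if orientation == "congener_ref":
        return tss(a, b, c, d)
    if orientation == "garden_ref":
        return tss(a, c, b, d)
    return 0.5 * (tss(a, b, c, d) + tss(a, c, b, d))


@dataclass
class PairOverlap:
    """Overlap record for one (garden plant, congener, scenario) pair."""

    garden_id: str
    congener_id: str
    genus: str
    scenario_id: str
    tss_overlap: float
    n_overlap_cells: int
    garden_range_cells: int
    congener_range_cells: int


def pair_overlaps(
    consensus: dict[str, BinaryMap],
    taxa: pd.DataFrame,
    scenario_id: str,
    orientation: str = "congener_ref",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All within-genus, life-form-matched garden x congener overlaps.

    ``consensus`` maps species_id to that species' consensus binary under
    one scenario. Returns ``(pairs, excluded)``; pairs whose TSS is
    undefined (empty margin) go to ``excluded`` with a reason.
    """
    gardens = taxa[taxa["group"] == "garden"]
    congeners = taxa[taxa["group"] == "congener"]
    rows, dropped = [], []
    for _, g in gardens.iterrows():
        if g["species_id"] not in consensus:
            continue
        gmap = consensus[g["species_id"]]
        partners = congeners[
            (congeners["genus"] == g["genus"])
            & (congeners["life_form"] == g["life_form"])
        ]
        for _, c in partners.iterrows():
            if c["species_id"] not in consensus:
                continue
            cmap = consensus[c["species_id"]]
            base = {
                "garden_id": g["species_id"],
                "congener_id": c["species_id"],
                "genus": g["genus"],
                "scenario_id": scenario_id,
            }
            try:
                t = overlap_tss(gmap, cmap, orientation=orientation)
            except DomainError as exc:
                dropped.append({**base, "reason": str(exc)})
                logger.info("pair %s/%s excluded: %s", g["species_id"], c["species_id"], exc)
                continue
            rows.append(
                {
                    **base,
                    "tss_overlap": t,
                    "n_overlap_cells": overlap_cells(gmap, cmap),
                    "garden_range_cells": range_size(gmap),
                    "congener_range_cells": range_size(cmap),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(dropped)


def summarize_per_garden(pairs: pd.DataFrame) -> pd.DataFrame:
    """Unweighted means of the pair metrics per garden plant and scenario."""
    if pairs.empty:
        return pd.DataFrame(
            columns=[
                "garden_id",
                "genus",
                "scenario_id",
                "mean_tss_overlap",
                "mean_overlap_cells",
                "n_congeners",
            ]
        )
    out = (
        pairs.groupby(["garden_id", "genus", "scenario_id"], as_index=False)
        .agg(
            mean_tss_overlap=("tss_overlap", "mean"),
            mean_overlap_cells=("n_overlap_cells", "mean"),
            n_congeners=("congener_id", "size"),
        )
        .sort_values(["scenario_id", "garden_id"], ignore_index=True)
    )
    return out
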