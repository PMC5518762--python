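"""Pseudo-absence designs and the presence/absence weighting contract.

Two schemes, one per model family: regression models (GLM/GAM) get a large
fixed number of background points drawn uniformly over land; machine-learning
models (BRT/RF) get as many pseudo-absences as the species has cleaned
occurrences, sampled outside an exclusion radius around them, with the draw
repeated to average out sampling noise. Case weights equalise the weighted
sums of presences and pseudo-absences in either scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (
    ClimateStack,
    DomainError,
    OccurrenceTable,
    great_circle_km,
)

logger = logging.getLogger(__name__)

_KM_PER_DEG = 111.19492664455873  # 2*pi*6371/360


@dataclass
class PseudoAbsenceSet:
    """Sampled absence points for one species under one scheme."""

    points: pd.DataFrame  # columns lon, lat
    scheme: str  # "random_10k" | "exclusion_radius"
    species_id: str = ""
    replicate_id: int = 0

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CaseWeights:
    """Per-row weights making presences and absences count equally in sum."""

    w_presence: float
    w_absence: float


def compute_weights(n_presence: int, n_pa: int) -> CaseWeights:
    """Presence weight 1; absence weight n_presence/n_pa, so the weighted
    sums of the two classes are equal."""
    if n_presence < 1 or n_pa < 1:
        raise DomainError("both class counts must be >= 1")
    return CaseWeights(w_presence=1.0, w_absence=n_presence / n_pa)


def _jitter_points(
    rng: np.random.Generator, stack: ClimateStack, rows: np.ndarray, cols: np.ndarray
) -> pd.DataFrame:
    res = stack.resolution
    lon = stack.lon_centers()[cols] + rng.uniform(-0.5, 0.5, len(cols)) * res
    lat = stack.lat_centers()[rows] + rng.uniform(-0.5, 0.5, len(rows)) * res
    return pd.DataFrame({"lon": lon, "lat": lat})


def sample_random_pa(
    stack: ClimateStack, n: int = 10_000, seed: int = 0, species_id: str = ""
) -> PseudoAbsenceSet:
    """Background absences: cells uniform over land, one jittered point each draw."""
    rows_all, cols_all = np.nonzero(stack.land_mask)
    if len(rows_all) == 0:
        raise DomainError("stack has no land cells")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(rows_all), size=n)
    pts = _jitter_points(rng, stack, rows_all[pick], cols_all[pick])
    return PseudoAbsenceSet(pts, scheme="random_10k", species_id=species_id)


def sample_exclusion_pa(
    occ: OccurrenceTable,
    stack: ClimateStack,
    exclusion_km: float = 200.0,
    replicates: int = 10,
    seed: int = 0,
) -> list[PseudoAbsenceSet]:
    """Exclusion-radius absences: |occ| points per replicate, all farther than
    ``exclusion_km`` from every cleaned occurrence of the species.

    Eligibility is judged at cell centers against an effective radius of
    ``exclusion_km`` plus half the cell diagonal, so the jittered point can
    never slip back inside the nominal radius. Cells are drawn without
    replacement when enough are eligible, with replacement otherwise
    (logged).
    """
    if not occ.cleaned:
        raise DomainError("exclusion sampling requires cleaned occurrences")
    species = occ.species()
    if len(species) != 1:
        raise DomainError("one species per exclusion-PA call")
    sp = species[0]
    if len(occ) == 0:
        raise DomainError(f"species {sp!r} has no occurrences")

    rows_all, cols_all = np.nonzero(stack.land_mask)
    clon = stack.lon_centers()[cols_all]
    clat = stack.lat_centers()[rows_all]
    olon = occ.records["lon"].to_numpy()
    olat = occ.records["lat"].to_numpy()
    # min distance from each land-cell center to any occurrence
    d = great_circle_km(
        clon[:, None], clat[:, None], olon[None, :], olat[None, :]
    )
    min_d = np.asarray(d).min(axis=1)
    half_diag = 0.5 * stack.resolution * _KM_PER_DEG * np.sqrt(2.0)
    eligible = min_d > exclusion_km + half_diag
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise DomainError(
            f"species {sp!r}: no cell farther than {exclusion_km} km from its "
            "occurrences (degenerate geometry)"
        )
    erows = rows_all[eligible]
    ecols = cols_all[eligible]
    n_points = len(occ)
    with_replacement = n_eligible < n_points
    if with_replacement:
        logger.info(
            "species %s: only %d eligible cells for %d pseudo-absences; "
            "sampling with replacement",
            sp,
            n_eligible,
            n_points,
        )
    master = np.random.default_rng(seed)
    out = []
    for rep in range(1, replicates + 1):
        sub = np.random.default_rng(master.integers(2**31 - 1))
        pick = (
            sub.integers(0, n_eligible, size=n_points)
            if with_replacement
            else sub.choice(n_eligible, size=n_points, replace=False)
        )
        pts = _jitter_points(sub, stack, erows[pick], ecols[pick])
        out.append(
            PseudoAbsenceSet(
                pts, scheme="exclusion_radius", species_id=sp, replicate_id=rep
            )
        )
    return out


def export_pa_sets(sets: list[PseudoAbsenceSet]) -> pd.DataFrame:
    """Occurrence-style long table with scheme and replicate columns."""
    frames = []
    for s in sets:
        df = s.points.copy()
        df.insert(0, "species_id", s.species_id)
        df["scheme"] = s.scheme
        df["replicate_id"] = s.replicate_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
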