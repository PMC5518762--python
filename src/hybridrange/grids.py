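"""Gridded climate stacks, occurrence tables, geodesic distance, and file I/O.

The prediction domain is a regular lon/lat grid (geographic CRS). Cells are
half-open: a cell owns its western and northern edges, ``[west, east) x
(south, north]``, so boundary points are never assigned twice. Row 0 is the
northernmost row. Water cells carry NaN in every climate layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: default bioclim predictor set: temperature seasonality, max temp of the
#: warmest month, min temp of the coldest month, precipitation of the
#: wettest / driest / warmest quarter
DEFAULT_VARIABLES = ("BIO4", "BIO5", "BIO6", "BIO16", "BIO17", "BIO18")

_BOUNDARY_SNAP = 1e-9  # tolerance for snapping points sitting on cell edges


class DomainError(ValueError):
    """A point, value or request outside the valid domain of an operation."""


class FormatError(ValueError):
    """A malformed or inconsistent file/table."""


@dataclass
class ClimateStack:
    """Multi-layer climate surface on a regular lon/lat grid.

    Parameters
    ----------
    layers : dict of str -> 2-D ndarray
        One grid per climate variable; NaN on water cells.
    extent : (west, east, south, north) in decimal degrees.
    resolution : cell size in degrees (the study analogue of 10' is 1/6).
    land_mask : 2-D bool array, True on land.
    scenario_id : scenario label, "BASE" for current climate.
    crs : geographic CRS identifier; only lon/lat is supported.
    """

    layers: dict[str, np.ndarray]
    extent: tuple[float, float, float, float]
    resolution: float
    land_mask: np.ndarray
    scenario_id: str = "BASE"
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if not self.layers:
            raise FormatError("a ClimateStack needs at least one layer")
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        shape = self.land_mask.shape
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise FormatError("layer names must be unique")
        for name in names:
            arr = np.asarray(self.layers[name], dtype=float)
            if arr.shape != shape:
                raise FormatError(
                    f"layer {name!r} has shape {arr.shape}, mask has {shape}"
                )
            arr = arr.copy()
            arr[~self.land_mask] = np.nan
            self.layers[name] = arr
        west, east, south, north = self.extent
        if not (west < east and south < north):
            raise FormatError(f"degenerate extent {self.extent}")
        nrows, ncols = shape
        if not (
            np.isclose(east - west, ncols * self.resolution, rtol=1e-6)
            and np.isclose(north - south, nrows * self.resolution, rtol=1e-6)
        ):
            raise FormatError("extent, resolution and grid shape disagree")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def nrows(self) -> int:
        return self.land_mask.shape[0]

    @property
    def ncols(self) -> int:
        return self.land_mask.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def lon_centers(self) -> np.ndarray:
        west = self.extent[0]
        return west + (np.arange(self.ncols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        north = self.extent[3]
        return north - (np.arange(self.nrows) + 0.5) * self.resolution

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return float(self.lon_centers()[col]), float(self.lat_centers()[row])

    def land_frame(self) -> pd.DataFrame:
        """Climate values of all land cells, one row per cell.

        Index is the flat ``cell_id = row*ncols + col``; columns are the
        climate variables plus the cell-center ``lon``/``lat``.
        """
        rows, cols = np.nonzero(self.land_mask)
        data = {name: self.layers[name][rows, cols] for name in self.layers}
        data["lon"] = self.lon_centers()[cols]
        data["lat"] = self.lat_centers()[rows]
        return pd.DataFrame(data, index=rows * self.ncols + cols)

    def with_layers(self, layers: dict[str, np.ndarray], scenario_id: str) -> "ClimateStack":
        return replace(self, layers=layers, scenario_id=scenario_id)


@dataclass(frozen=True)
class CellIndex:
    """0-based grid cell address; row 0 is the northernmost row."""

    row: int
    col: int
    ncols: int

    @property
    def cell_id(self) -> int:
        return self.row * self.ncols + self.col


@dataclass
class OccurrenceTable:
    """Species-tagged point records in decimal degrees.

    ``records`` columns: ``species_id``, ``lon``, ``lat`` and optionally
    ``source_tag``. ``cleaned`` is True once grid-cell deduplication and the
    water-body screen have run.
    """

    records: pd.DataFrame
    cleaned: bool = False

    def __post_init__(self) -> None:
        missing = {"species_id", "lon", "lat"} - set(self.records.columns)
        if missing:
            raise FormatError(f"occurrence table lacks columns {sorted(missing)}")
        bad = ~(
            self.records["lon"].between(-180, 180)
            & self.records["lat"].between(-90, 90)
        )
        if bad.any():
            idx = self.records.index[bad][0]
            raise FormatError(f"row {idx}: coordinates out of bounds")

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        return list(pd.unique(self.records["species_id"]))


@dataclass
class SuitabilityMap:
    """Continuous per-cell suitability in [0, 1]; NaN on water."""

    values: np.ndarray
    species_id: str = ""
    scenario_id: str = "BASE"


@dataclass
class BinaryMap:
    """Thresholded suitability: 1 suitable, 0 unsuitable, NaN water."""

    values: np.ndarray
    species_id: str = ""
    scenario_id: str = "BASE"


def _snap(x: np.ndarray) -> np.ndarray:
    """Snap near-integer grid offsets onto the integer before flooring."""
    r = np.round(x)
    return np.where(np.abs(x - r) < _BOUNDARY_SNAP, r, x)


def cells_of(
    lon: np.ndarray, lat: np.ndarray, stack: ClimateStack
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cell lookup; returns (rows, cols) arrays.

    Cells are half-open ``[west, east) x (south, north]``. Raises
    :class:`DomainError` if any point lies outside the extent.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    west, east, south, north = stack.extent
    res = stack.resolution
    u = _snap((lon - west) / res)
    v = _snap((north - lat) / res)
    cols = np.floor(u).astype(int)
    rows = np.floor(v).astype(int)
    # northern extent edge belongs to row 0 (interval closed at the top)
    rows = np.where(v == 0.0, 0, rows)
    out = (cols < 0) | (cols >= stack.ncols) | (rows < 0) | (rows >= stack.nrows)
    # lat exactly on the southern extent edge falls outside ((south, north])
    out |= v >= stack.nrows + _BOUNDARY_SNAP
    if out.any():
        i = int(np.nonzero(out)[0][0]) if lon.ndim else 0
        raise DomainError(
            f"point ({np.atleast_1d(lon)[i]}, {np.atleast_1d(lat)[i]}) "
            f"outside extent {stack.extent}"
        )
    return rows, cols


def cell_of(lon: float, lat: float, stack: ClimateStack) -> CellIndex:
    """Grid cell containing a point (half-open footprints, see module doc)."""
    rows, cols = cells_of(np.asarray([lon]), np.asarray([lat]), stack)
    return CellIndex(int(rows[0]), int(cols[0]), stack.ncols)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine distance in km on a sphere of radius 6371 km; broadcasts."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.isscalar(d) or d.ndim == 0:
        return float(d)
    return d


def clean_occurrences(occ: OccurrenceTable, stack: ClimateStack) -> OccurrenceTable:
    """Thin records to one per species per grid cell and drop water records.

    Records outside the grid extent are treated like water records (clearly
    erroneous) and dropped. Within a cell the first record in input order is
    kept. Species left with no records are reported with a warning; callers
    exclude them downstream.
    """
    df = occ.records.reset_index(drop=True)
    west, east, south, north = stack.extent
    inside = (
        (df["lon"] >= west)
        & (df["lon"] < east)
        & (df["lat"] > south)
        & (df["lat"] <= north)
    )
    n_outside = int((~inside).sum())
    df = df[inside]
    if len(df):
        rows, cols = cells_of(df["lon"].to_numpy(), df["lat"].to_numpy(), stack)
        on_land = stack.land_mask[rows, cols]
        n_water = int((~on_land).sum())
        df = df.assign(_cell=rows * stack.ncols + cols)[on_land]
        df = df.drop_duplicates(subset=["species_id", "_cell"], keep="first")
        df = df.drop(columns="_cell")
    else:
        n_water = 0
    if n_outside or n_water:
        logger.info(
            "clean_occurrences: dropped %d out-of-extent and %d water records",
            n_outside,
            n_water,
        )
    lost = set(occ.records["species_id"]) - set(df["species_id"])
    for sp in sorted(lost):
        warnings.warn(
            f"species {sp!r} has no records left after cleaning", stacklevel=2
        )
    return OccurrenceTable(df.reset_index(drop=True), cleaned=True)


# -- file I/O -------------------------------------------------------------

_MASK_VAR = "land_mask"


def write_climate(stack: ClimateStack, path) -> None:
    """Write a stack as a multi-layer NetCDF raster (NaN = no-data)."""
    lat = stack.lat_centers()
    lon = stack.lon_centers()
    data = {
        name: (("lat", "lon"), stack.layers[name]) for name in stack.layers
    }
    data[_MASK_VAR] = (("lat", "lon"), stack.land_mask.astype(np.int8))
    ds = xr.Dataset(
        data,
        coords={"lat": lat, "lon": lon},
        attrs={
            "extent": list(stack.extent),
            "resolution": stack.resolution,
            "scenario_id": stack.scenario_id,
            "crs": stack.crs,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_climate(path) -> ClimateStack:
    """Read a stack written by :func:`write_climate`; round-trip identity."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for attr in ("extent", "resolution", "scenario_id", "crs"):
        if attr not in ds.attrs:
            raise FormatError(f"climate file lacks attribute {attr!r}")
    crs = str(ds.attrs["crs"])
    if crs != "EPSG:4326":
        raise FormatError(f"unsupported CRS {crs!r}; only EPSG:4326 lon/lat")
    if _MASK_VAR not in ds:
        raise FormatError("climate file lacks the land mask layer")
    mask = ds[_MASK_VAR].values.astype(bool)
    layers = {
        str(name): ds[name].values.astype(float)
        for name in ds.data_vars
        if name != _MASK_VAR
    }
    return ClimateStack(
        layers=layers,
        extent=tuple(float(x) for x in np.asarray(ds.attrs["extent"])),
        resolution=float(ds.attrs["resolution"]),
        land_mask=mask,
        scenario_id=str(ds.attrs["scenario_id"]),
        crs=crs,
    )


def write_occurrences(occ: OccurrenceTable, path) -> None:
    occ.records.to_csv(path, index=False)


def read_occurrences(path, cleaned: bool = False) -> OccurrenceTable:
    df = pd.read_csv(path)
    missing = {"species_id", "lon", "lat"} - set(df.columns)
    if missing:
        raise FormatError(f"occurrence CSV lacks columns {sorted(missing)}")
    return OccurrenceTable(df, cleaned=cleaned)


def read_taxa(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_taxa(df)


def write_taxa(taxa: pd.DataFrame, path) -> None:
    taxa.to_csv(path, index=False)


def validate_taxa(taxa: pd.DataFrame) -> pd.DataFrame:
    """Check the garden/congener taxon table invariants.

    Every garden species must have at least one congener of the same genus
    and life form (the potential hybridisation partners the pairing step
    will use); congeners carry a native/naturalized status.
    """
    required = {"species_id", "genus", "group", "life_form"}
    missing = required - set(taxa.columns)
    if missing:
        raise FormatError(f"taxon table lacks columns {sorted(missing)}")
    if taxa["genus"].isna().any() or (taxa["genus"].astype(str) == "").any():
        raise FormatError("taxon table has empty genus entries")
    bad_group = set(taxa["group"]) - {"garden", "congener"}
    if bad_group:
        raise FormatError(f"unknown group labels {sorted(bad_group)}")
    congeners = taxa[taxa["group"] == "congener"]
    for _, row in taxa[taxa["group"] == "garden"].iterrows():
        partners = congeners[
            (congeners["genus"] == row["genus"])
            & (congeners["life_form"] == row["life_form"])
        ]
        if partners.empty:
            raise FormatError(
                f"garden species {row['species_id']!r} has no congener with "
                "matching genus and life form"
            )
    return taxa


def write_results_table(df: pd.DataFrame, path) -> None:
    """Write a long-format results table as CSV (one row per record)."""
    df.to_csv(path, index=False)
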