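"""Gridded climate scenarios and species occurrence records.

A *climate scenario* is a stack of co-registered raster layers, one per
climate variable, for a single time slice (its age in Ma before present).
Rasters use the cell-registered ESRI ASCII grid dialect: a header with
``ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value`` followed by
``nrows`` rows of whitespace-separated values, row 0 being the
northernmost row.

Occurrence records are plain (longitude, latitude) presence points per
species, as exported from biodiversity portals.  Cleaning is deterministic:
exact coordinate duplicates are dropped, as are points that fall outside
the grid or on a nodata cell of any layer (e.g. herbarium records of
coastal species digitised into the ocean).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClimateLayer",
    "ClimateScenario",
    "OccurrenceSet",
    "CleaningReport",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_scenario",
    "write_scenario",
    "read_occurrences",
    "write_occurrences",
    "sample_values",
    "clean_occurrences",
]

DEFAULT_NODATA = -9999.0


@dataclass
class ClimateLayer:
    """One gridded climate variable.

    Parameters
    ----------
    variable_name
        Name of the climate variable (temperatures in degC, precipitation
        in mm/day by convention; any user-defined name is accepted).
    grid
        2-D float array; row 0 is the northernmost row.
    origin
        (west longitude, north latitude) of the grid's top-left corner,
        decimal degrees.
    cell_size
        Cell edge length in degrees (> 0).
    nodata_value
        Sentinel marking missing cells.
    """

    variable_name: str
    grid: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        data = self.grid[self.grid != self.nodata_value]
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("grid contains non-finite values that are not nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.grid == self.nodata_value

    def values_masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_equal(self.grid, self.nodata_value)


@dataclass
class ClimateScenario:
    """Named stack of co-registered climate layers for one time slice."""

    name: str
    age_ma: float
    layers: list[ClimateLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_ma < 0:
            raise ValueError("age_ma must be non-negative")
        self._check_coregistered()

    def _check_coregistered(self) -> None:
        if not self.layers:
            return
        ref = self.layers[0]
        names: set[str] = set()
        for lay in self.layers:
            if lay.variable_name in names:
                raise ValueError(f"duplicate variable name {lay.variable_name!r}")
            names.add(lay.variable_name)
            if lay.shape != ref.shape:
                raise ValueError(
                    f"layer {lay.variable_name!r} shape {lay.shape} != {ref.shape}"
                )
            if not np.allclose(lay.origin, ref.origin) or not np.isclose(
                lay.cell_size, ref.cell_size
            ):
                raise ValueError(f"layer {lay.variable_name!r} is not co-registered")

    @property
    def variable_names(self) -> list[str]:
        return [lay.variable_name for lay in self.layers]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def origin(self) -> tuple[float, float]:
        return self.layers[0].origin

    @property
    def cell_size(self) -> float:
        return self.layers[0].cell_size

    def layer(self, variable_name: str) -> ClimateLayer:
        for lay in self.layers:
            if lay.variable_name == variable_name:
                return lay
        raise KeyError(f"variable {variable_name!r} not in scenario {self.name!r}")

    def nodata_mask(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """Union of nodata masks over the given (default: all) variables."""
        names = list(variables) if variables is not None else self.variable_names
        mask = np.zeros(self.shape, dtype=bool)
        for name in names:
            mask |= self.layer(name).mask
        return mask

    def values_stack(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """(n_variables, nrows, ncols) stack in the requested order."""
        names = list(variables) if variables is not None else self.variable_names
        return np.stack([self.layer(n).grid for n in names])

    def point_to_cell(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a lon/lat point to its containing (row, col), or None.

        Cells are half-open: ``[x, x + cell)`` in longitude and
        ``(y - cell, y]`` in latitude going south from the north edge, so
        every point interior to the grid belongs to exactly one cell.
        """
        west, north = self.origin
        cs = self.cell_size
        nrows, ncols = self.shape
        col = int(np.floor((lon - west) / cs))
        # latitude: row r covers (north - (r+1)*cs, north - r*cs], i.e. the
        # top edge of a cell belongs to it; floor((north - lat)/cs) selects
        # exactly that row for boundary and interior points alike
        row = int(np.floor((north - lat) / cs))
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None


@dataclass
class OccurrenceSet:
    """Georeferenced presence points for one species."""

    species: str
    points: list[tuple[float, float]]  # (lon, lat)
    source: str = ""

    def __post_init__(self) -> None:
        for lon, lat in self.points:
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(f"coordinate out of range: ({lon}, {lat})")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CleaningReport:
    species: str
    n_input: int
    n_duplicates: int
    n_invalid: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_duplicates - self.n_invalid


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path, variable_name: str | None = None) -> ClimateLayer:
    """Read a cell-registered ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while len(header) < 6:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated header")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = fh.read()
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header key {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    grid = np.loadtxt(io.StringIO(body), dtype=float)
    grid = np.atleast_2d(grid)
    if grid.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows}x{ncols} values, got {grid.size}"
        )
    grid = grid.reshape(nrows, ncols)
    north = header["yllcorner"] + nrows * header["cellsize"]
    return ClimateLayer(
        variable_name=variable_name or path.stem,
        grid=grid,
        origin=(header["xllcorner"], north),
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )


def write_ascii_grid(layer: ClimateLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid, preserving values exactly."""
    path = Path(path)
    nrows, ncols = layer.shape
    west, north = layer.origin
    yll = north - nrows * layer.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(west)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(layer.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(layer.nodata_value)!r}\n")
        for row in layer.grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_scenario(manifest_path: str | Path) -> ClimateScenario:
    """Read a scenario from a YAML manifest.

    The manifest lists ``name``, ``age_ma`` and ``layers`` as an ordered
    mapping of variable name to raster file (paths relative to the
    manifest).  Raises if a raster is missing or the layers are not
    co-registered.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    layers = []
    for var, fname in manifest["layers"].items():
        fpath = manifest_path.parent / fname
        if not fpath.exists():
            raise FileNotFoundError(f"raster for {var!r} not found: {fpath}")
        layers.append(read_ascii_grid(fpath, variable_name=var))
    return ClimateScenario(
        name=str(manifest["name"]),
        age_ma=float(manifest["age_ma"]),
        layers=layers,
    )


def write_scenario(scenario: ClimateScenario, directory: str | Path) -> Path:
    """Write every layer plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries: dict[str, str] = {}
    for lay in scenario.layers:
        fname = f"{lay.variable_name}.asc"
        write_ascii_grid(lay, directory / fname)
        entries[lay.variable_name] = fname
    manifest = {"name": scenario.name, "age_ma": scenario.age_ma, "layers": entries}
    manifest_path = directory / "scenario.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


# ---------------------------------------------------------------------------
# Occurrence I/O

def read_occurrences(path: str | Path) -> dict[str, OccurrenceSet]:
    """Read a ``species,lon,lat[,source]`` CSV into per-species sets."""
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"occurrence CSV must have columns {sorted(required)}")
    out: dict[str, OccurrenceSet] = {}
    for species, sub in df.groupby("species", sort=False):
        source = ""
        if "source" in sub.columns and len(sub):
            source = str(sub["source"].iloc[0])
        out[str(species)] = OccurrenceSet(
            species=str(species),
            points=list(zip(sub["lon"].astype(float), sub["lat"].astype(float))),
            source=source,
        )
    return out


def write_occurrences(occ_sets: Iterable[OccurrenceSet], path: str | Path) -> None:
    rows = [
        {"species": occ.species, "lon": lon, "lat": lat, "source": occ.source}
        for occ in occ_sets
        for lon, lat in occ.points
    ]
    pd.DataFrame(rows, columns=["species", "lon", "lat", "source"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Sampling and cleaning

def sample_values(
    scenario: ClimateScenario,
    points: Sequence[tuple[float, float]],
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sample every layer at the cells containing the given points.

    Returns a DataFrame with columns ``lon, lat, row, col, valid`` plus one
    column per variable.  Points outside the grid, or on a cell that is
    nodata in any sampled layer, are flagged ``valid=False`` and keep NaN
    values; they are never silently dropped.
    """
    if not scenario.layers:
        raise ValueError("scenario has no layers")
    names = list(variables) if variables is not None else scenario.variable_names
    stack = scenario.values_stack(names)
    bad = scenario.nodata_mask(names)
    records = []
    for lon, lat in points:
        cell = scenario.point_to_cell(lon, lat)
        rec: dict[str, object] = {"lon": lon, "lat": lat}
        if cell is None or bad[cell]:
            rec.update(row=-1 if cell is None else cell[0],
                       col=-1 if cell is None else cell[1], valid=False)
            rec.update({n: np.nan for n in names})
        else:
            r, c = cell
            rec.update(row=r, col=c, valid=True)
            rec.update({n: stack[i, r, c] for i, n in enumerate(names)})
        records.append(rec)
    return pd.DataFrame(records, columns=["lon", "lat", "row", "col", "valid", *names])


def clean_occurrences(
    occ: OccurrenceSet, scenario: ClimateScenario
) -> tuple[OccurrenceSet, CleaningReport]:
    """Drop exact coordinate duplicates and points invalid on the grid.

    Replaces by-eye curation with a deterministic rule: a point is removed
    if its coordinates duplicate an earlier point exactly, or if it falls
    outside the scenario grid or on a nodata cell of any layer.
    """
    seen: set[tuple[float, float]] = set()
    deduped: list[tuple[float, float]] = []
    n_dup = 0
    for pt in occ.points:
        if pt in seen:
            n_dup += 1
        else:
            seen.add(pt)
            deduped.append(pt)
    table = sample_values(scenario, deduped)
    valid = table["valid"].to_numpy()
    kept = [pt for pt, ok in zip(deduped, valid) if ok]
    n_invalid = int((~valid).sum())
    if not kept:
        warnings.warn(f"{occ.species}: no valid occurrences after cleaning")
    report = CleaningReport(
        species=occ.species,
        n_input=len(occ.points),
        n_duplicates=n_dup,
        n_invalid=n_invalid,
    )
    return OccurrenceSet(occ.species, kept, occ.source), report
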