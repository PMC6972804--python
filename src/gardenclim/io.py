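"""Reading and writing the pipeline's file formats.

Trait tables are CSV files with explicit column mapping (no header
guessing), rasters are ESRI ASCII grids or GeoTIFFs, and the
per-population climate-of-origin table ships with the package.  All
numeric outputs elsewhere in the package are plain CSV/JSON so that a
full analysis round-trips through human-readable files.

Raster convention: row 0 is the northernmost row, cell-centre
registration, coordinates continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gardenclim")

#: canonical design columns of a plantation trait table
DESIGN_COLUMNS = ("tree_id", "block", "population", "family")

#: the seven climate-of-origin variables used throughout the analysis
CLIMATE_VARIABLES = ("T_MA", "T_MAX", "T_RANGE", "P_MA", "P_DM", "P_RANGE", "AI_inv")

#: measured trait names with display units
TRAIT_UNITS = {
    "PRI": "unitless",
    "NDVI": "unitless",
    "LS": "cm^2",
    "SLA": "mm^2/mg",
    "d13C": "per-mil",
    "N_CONC": "%",
    "WD": "g/cm^3",
}


class SchemaError(ValueError):
    """A required design column is missing from the input file."""


class ValidationError(ValueError):
    """The parsed table violates a trait-table invariant."""


class RasterAlignmentError(ValueError):
    """Rasters in a stack disagree in shape or georeference."""


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Tree-level records from the plantation: design cells plus traits.

    ``data`` holds one row per tree with the design columns
    ``tree_id, block, population, family`` and one column per trait.
    Missing trait values are ``NaN`` and propagate as missing through
    every downstream stage (complete-case per model fit).
    """

    data: pd.DataFrame
    trait_names: list[str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_trait_table(self.data, self.trait_names)

    @property
    def n_trees(self) -> int:
        return len(self.data)

    def traits(self) -> pd.DataFrame:
        return self.data[self.trait_names]

    def with_trait(self, name: str, values: pd.Series | np.ndarray) -> "TraitTable":
        """Return a copy with one trait column added or replaced."""
        df = self.data.copy()
        df[name] = np.asarray(values, dtype=float)
        names = self.trait_names if name in self.trait_names else self.trait_names + [name]
        return TraitTable(df, list(names), dict(self.units))

    def subset_populations(self, populations: Sequence[str]) -> "TraitTable":
        keep = self.data["population"].isin(list(populations))
        return TraitTable(self.data.loc[keep].reset_index(drop=True),
                          list(self.trait_names), dict(self.units))


def validate_trait_table(df: pd.DataFrame, trait_names: Sequence[str]) -> None:
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing design column {col!r}")
    dup = df["tree_id"][df["tree_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate tree id {dup.iloc[0]!r}")
    fam_pops = df.groupby("family", observed=True)["population"].nunique()
    bad = fam_pops[fam_pops > 1]
    if len(bad):
        raise ValidationError(
            f"family {bad.index[0]!r} appears under {bad.iloc[0]} populations")
    for t in trait_names:
        if t not in df.columns:
            raise SchemaError(f"missing trait column {t!r}")
        vals = df[t].to_numpy()
        if np.isinf(vals).any():
            raise ValidationError(f"non-finite (infinite) value in trait {t!r}")


def read_trait_table(path: str | Path,
                     schema: Mapping[str, str] | None = None,
                     trait_columns: Mapping[str, str] | None = None) -> TraitTable:
    """Read a tree-level trait table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Mapping from canonical design names (``tree_id``, ``block``,
        ``population``, ``family``) to the column names used in the
        file.  Omitted entries default to the canonical name itself.
    trait_columns
        Mapping from trait name to file column.  When ``None``, every
        non-design column is treated as a trait.

    Unparseable trait cells are retained as missing and counted in the
    log; design cells must parse.
    """
    df = pd.read_csv(path, dtype=str).rename(
        columns={v: k for k, v in (schema or {}).items()})
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing design column {col!r} in {path}")
    if trait_columns is None:
        trait_columns = {c: c for c in df.columns if c not in DESIGN_COLUMNS}
    else:
        df = df.rename(columns={v: k for k, v in trait_columns.items()
                                if v != k})
    out = df[list(DESIGN_COLUMNS)].copy()
    n_missing = 0
    for trait in trait_columns:
        parsed = pd.to_numeric(df[trait], errors="coerce")
        n_missing += int(parsed.isna().sum() - df[trait].isna().sum())
        out[trait] = parsed
    if n_missing:
        logger.info("read_trait_table: %d unparseable trait cells set missing",
                    n_missing)
    return TraitTable(out, list(trait_columns), dict(TRAIT_UNITS))


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# climate variables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateVariableSet:
    """Values of the seven climate-of-origin variables for one location.

    Temperatures in deg C, precipitation in mm, ``AI_inv`` unitless
    (evapotranspiration over precipitation; larger = more arid).
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CLIMATE_VARIABLES) - set(self.values)
        if missing:
            raise ValueError(f"missing climate variables: {sorted(missing)}")
        v = self.values
        if v["P_MA"] < 0 or v["P_DM"] < 0 or v["P_RANGE"] < 0:
            raise ValueError("precipitation must be >= 0")
        if v["T_MAX"] < v["T_MA"]:
            raise ValueError("T_MAX must be >= T_MA")
        if v["AI_inv"] <= 0:
            raise ValueError("AI_inv must be > 0")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def inverse_aridity(p_ma: float, evapotranspiration: float) -> float:
    """Inverse aridity index: mean annual evapotranspiration over
    mean annual precipitation.  Larger values mean a more arid climate,
    which reads more intuitively than the conventional P/PET ratio.
    """
    if p_ma <= 0 or evapotranspiration <= 0:
        raise ValueError("precipitation and evapotranspiration must be > 0")
    return evapotranspiration / p_ma


def load_population_climate() -> pd.DataFrame:
    """Climate-of-origin for the 12 source populations of the trial.

    Columns: population, climate_zone, latitude, longitude, T_MAX (deg C),
    P_MA (mm), AI_inv, P_DM (mm), plus the family counts of the two
    study data sets.  Values are the published station extractions for
    the provenance trial; the remaining three variables (T_MA, T_RANGE,
    P_RANGE) are site-specific raster extractions not tabulated here and
    are synthesised by :mod:`gardenclim.simulate` when needed.
    """
    with resources.files("gardenclim.data").joinpath(
            "populations_climate.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


@dataclass
class RasterGrid:
    """A single-band georeferenced grid.

    ``values`` is a float array with ``NaN`` marking nodata cells;
    ``x_origin``/``y_origin`` locate the outer corner of the top-left
    (northernmost) cell and ``cell_size`` is the square cell edge.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    scenario: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask (True = missing)."""
        return np.isnan(self.values)

    def georeference(self) -> tuple[float, float, float]:
        return (self.x_origin, self.y_origin, self.cell_size)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.georeference(), other.georeference()))

    def with_values(self, values: np.ndarray, scenario: str | None = None) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float),
                       scenario=self.scenario if scenario is None else scenario)


def read_esri_ascii(path: str | Path, scenario: str = "current") -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).  Rows are stored north to south,
    matching this package's row-0-is-north convention."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.array(rows, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    cell = header["cellsize"]
    return RasterGrid(values,
                      x_origin=header["xllcorner"],
                      y_origin=header["yllcorner"] + nrows * cell,
                      cell_size=cell, scenario=scenario)


def write_esri_ascii(grid: RasterGrid, path: str | Path,
                     nodata: float = -9999.0) -> None:
    nrows, ncols = grid.shape
    vals = np.where(grid.mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n"
                 f"nrows {nrows}\n"
                 f"xllcorner {grid.x_origin!r}\n"
                 f"yllcorner {grid.y_origin - nrows * grid.cell_size!r}\n"
                 f"cellsize {grid.cell_size!r}\n"
                 f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(grid: RasterGrid, path: str | Path,
                  nodata: float = -9999.0) -> None:
    """Write a single-band GeoTIFF with pixel-scale/tiepoint georeference
    tags and a GDAL-style nodata tag."""
    import tifffile

    vals = np.where(grid.mask, nodata, grid.values).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path: str | Path, scenario: str = "current") -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else (0.0,) * 6
        nodata_tag = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else None
    if nodata_tag is not None:
        values[values == float(nodata_tag)] = np.nan
    return RasterGrid(values, x_origin=float(tie[3]), y_origin=float(tie[4]),
                      cell_size=float(scale[0]), scenario=scenario)


def read_raster(path: str | Path, scenario: str = "current") -> RasterGrid:
    """Dispatch on file suffix: ``.asc`` -> ESRI ASCII, else GeoTIFF."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd"):
        return read_esri_ascii(path, scenario)
    return read_geotiff(path, scenario)


def read_raster_stack(paths: Sequence[str | Path], variables: Sequence[str],
                      scenario: str = "current") -> dict[str, RasterGrid]:
    """Load co-registered climate layers into a stack keyed by variable.

    Nodata is harmonised to the union mask: a cell missing in any layer
    is missing in all returned layers.
    """
    if len(paths) != len(variables):
        raise ValueError("need one path per variable")
    grids = {var: read_raster(p, scenario) for var, p in zip(variables, paths)}
    return align_stack(grids)


def align_stack(grids: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """Verify co-registration and apply the union nodata mask in place."""
    first = next(iter(grids.values()))
    for name, g in grids.items():
        if not first.same_grid(g):
            raise RasterAlignmentError(
                f"layer {name!r} shape/georeference mismatch: "
                f"{g.shape}/{g.georeference()} vs {first.shape}/{first.georeference()}")
    union = np.zeros(first.shape, dtype=bool)
    for g in grids.values():
        union |= g.mask
    for g in grids.values():
        g.values[union] = np.nan
    return grids
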