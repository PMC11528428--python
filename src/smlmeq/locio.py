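"""Localization-table and molecule-map I/O, plus run configuration.

Internal units are fixed: nanometres for coordinates and localization
precision, square micrometres for areas, seconds for times.  Unit
conversion happens only at the I/O boundary (``read_localizations``
accepts micrometre or camera-pixel inputs and converts on read).

Two tabular containers cross the module boundaries:

``LocalizationTable``
    raw SMLM localizations (x, y, frame, optional precision / species)
    with table-level acquisition metadata (frame interval and count).
``MoleculeMap``
    positions of counted protein molecules -- either the output of the
    qPAINT counting stage or simulation ground truth -- with a species
    label per point and an integer ``count_weight`` (number of molecules,
    or docking sites, represented by the point).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, ParameterError, ParseError

logger = logging.getLogger("smlmeq")

_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "micron": 1000.0}

#: canonical field names a column map may target
_CANONICAL = ("x", "y", "frame", "precision", "species")


@dataclass
class LocalizationTable:
    """SMLM localizations in nm, one row per localization."""

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    precision: np.ndarray | None = None
    species: np.ndarray | None = None
    frame_interval_s: float = 0.1
    frame_count: int | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.frame = np.asarray(self.frame, dtype=np.int64)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError("localization coordinates must be finite")
        if self.frame.size and self.frame.min() < 0:
            raise DataError("frame indices must be >= 0")
        if self.frame_count is None:
            self.frame_count = int(self.frame.max()) + 1 if self.frame.size else 0
        if self.frame.size and self.frame.max() >= self.frame_count:
            raise DataError(
                f"frame index {int(self.frame.max())} outside frame_count "
                f"{self.frame_count}"
            )
        if self.precision is not None:
            self.precision = np.asarray(self.precision, dtype=float)
            if np.any(~(self.precision > 0)):
                raise DataError("localization precision must be > 0 where present")
        if self.species is not None:
            self.species = np.asarray(self.species)

    def __len__(self):
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x, self.y])


@dataclass
class MoleculeMap:
    """Counted molecule positions (nm) with species labels.

    At most two distinct species per analysis: homo-association uses a
    single label, hetero analyses exactly two.
    """

    x: np.ndarray
    y: np.ndarray
    species: np.ndarray
    count_weight: np.ndarray | None = None
    source_cluster: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.species = np.asarray(self.species)
        if self.count_weight is None:
            self.count_weight = np.ones(self.x.size, dtype=np.int64)
        self.count_weight = np.asarray(self.count_weight, dtype=np.int64)
        if np.any(self.count_weight < 1):
            raise DataError("count_weight must be >= 1")
        labels = np.unique(self.species)
        if labels.size > 2:
            raise DataError(
                f"at most 2 species supported, got {labels.size}: {list(labels)}"
            )
        if self.source_cluster is not None:
            self.source_cluster = np.asarray(self.source_cluster, dtype=np.int64)

    def __len__(self):
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def species_labels(self) -> list:
        return sorted(np.unique(self.species).tolist())

    def select(self, species) -> np.ndarray:
        """(n, 2) coordinates of one species, in nm."""
        mask = self.species == species
        return np.column_stack([self.x[mask], self.y[mask]])


@dataclass
class RunConfig:
    """Resolved pipeline parameters; mirrors the YAML config file.

    ``f_d``/``f_v``/``f_k`` are the expansion factors scaling the mean
    first nearest-neighbor distance into the Delaunay/Voronoi acceptance
    areas and the ks-density kernel width; ``th_constant`` is the
    ks-density rejection-threshold constant c in TH = c/(2*pi*sigma^2*N).
    """

    pixel_size_nm: float = 130.0  # camera pixel, for pixel-unit dialects
    f_d: float = 3.0
    f_v: float = 3.0
    f_k: float = 1.0
    th_constant: float = 1.5
    proximity_nm: float = 15.0
    tirf_depth_nm: float = 100.0
    seed: int = 0
    frame_interval_s: float = 0.1

    def __post_init__(self):
        for name in ("f_d", "f_v", "f_k", "th_constant"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (100.0 <= self.tirf_depth_nm <= 250.0):
            raise ConfigurationError(
                "tirf_depth_nm must lie in [100, 250] (TIRF evanescent depth)"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_localizations(
    path,
    dialect: str = "csv",
    column_map: dict | None = None,
    unit: str = "nm",
    pixel_size_nm: float | None = None,
    frame_interval_s: float = 0.1,
) -> LocalizationTable:
    """Read a localization table into nm coordinates.

    Parameters
    ----------
    path
        CSV file (``dialect="csv"``) or Picasso-style HDF5 file with a
        ``locs`` dataset (``dialect="picasso_hdf5"``, pixel units).
    column_map
        Mapping from file column name to canonical field name
        (``x``, ``y``, ``frame``, ``precision``, ``species``), e.g.
        ``{"x [nm]": "x"}`` for ThunderSTORM-style headers.
    unit
        Coordinate unit in the file: ``"nm"`` or ``"um"`` (CSV dialect).
    pixel_size_nm
        Camera pixel size; required for the pixel-unit HDF5 dialect.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"localization file not found: {path}")
    if dialect == "csv":
        return _read_csv_localizations(path, column_map, unit, frame_interval_s)
    if dialect == "picasso_hdf5":
        return _read_picasso_hdf5(path, pixel_size_nm, frame_interval_s)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def _read_csv_localizations(path, column_map, unit, frame_interval_s):
    if unit not in _UNIT_TO_NM:
        raise ConfigurationError(f"unknown coordinate unit {unit!r}")
    scale = _UNIT_TO_NM[unit]
    df = pd.read_csv(path)
    if column_map:
        bad = [t for t in column_map.values() if t not in _CANONICAL]
        if bad:
            raise ConfigurationError(f"column_map targets unknown fields: {bad}")
        missing = [src for src in column_map if src not in df.columns]
        if missing:
            raise ConfigurationError(
                f"mapped column(s) missing from {path.name}: {missing}"
            )
        df = df.rename(columns=column_map)
    for col in ("x", "y", "frame"):
        if col not in df.columns:
            raise ConfigurationError(
                f"required column {col!r} missing from {path.name} "
                "(use column_map to rename)"
            )
    coords = {}
    for col in ("x", "y"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric {col} value {df[col].iloc[row]!r} at data row {row}"
            )
        coords[col] = values.to_numpy() * scale
    precision = None
    if "precision" in df.columns:
        precision = pd.to_numeric(df["precision"]).to_numpy() * scale
    species = df["species"].to_numpy() if "species" in df.columns else None
    return LocalizationTable(
        x=coords["x"],
        y=coords["y"],
        frame=df["frame"].to_numpy(dtype=np.int64),
        precision=precision,
        species=species,
        frame_interval_s=frame_interval_s,
    )


def _read_picasso_hdf5(path, pixel_size_nm, frame_interval_s):
    import h5py

    if pixel_size_nm is None or pixel_size_nm <= 0:
        raise ConfigurationError(
            "pixel_size_nm is required for the picasso_hdf5 dialect"
        )
    with h5py.File(path, "r") as fh:
        if "locs" not in fh:
            raise ConfigurationError(f"no 'locs' dataset in {path.name}")
        locs = fh["locs"][()]
    names = locs.dtype.names or ()
    for col in ("x", "y", "frame"):
        if col not in names:
            raise ConfigurationError(f"required field {col!r} missing from 'locs'")
    precision = None
    if "lpx" in names and "lpy" in names:
        precision = 0.5 * (locs["lpx"] + locs["lpy"]) * pixel_size_nm
    return LocalizationTable(
        x=locs["x"] * pixel_size_nm,
        y=locs["y"] * pixel_size_nm,
        frame=locs["frame"].astype(np.int64),
        precision=precision,
        frame_interval_s=frame_interval_s,
    )


def write_molecule_map(molecules: MoleculeMap, path) -> None:
    """Write a molecule map as CSV (columns x_nm, y_nm, species, count_weight)."""
    if len(molecules) == 0:
        raise ParameterError("refusing to write an empty molecule map")
    df = pd.DataFrame(
        {
            "x_nm": molecules.x,
            "y_nm": molecules.y,
            "species": molecules.species,
            "count_weight": molecules.count_weight,
        }
    )
    if molecules.source_cluster is not None:
        df["source_cluster"] = molecules.source_cluster
    df.to_csv(path, index=False, float_format="%.6f")


def read_molecule_map(path) -> MoleculeMap:
    """Read back a molecule map written by :func:`write_molecule_map`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"molecule map not found: {path}")
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm", "species"):
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} missing from {path.name}")
    return MoleculeMap(
        x=df["x_nm"].to_numpy(float),
        y=df["y_nm"].to_numpy(float),
        species=df["species"].to_numpy(),
        count_weight=df["count_weight"].to_numpy(np.int64)
        if "count_weight" in df.columns
        else None,
        source_cluster=df["source_cluster"].to_numpy(np.int64)
        if "source_cluster" in df.columns
        else None,
    )
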