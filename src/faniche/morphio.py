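"""File formats and the validated in-memory data model.

Three external formats are supported:

* TPS landmark files (the TpsDig2 dialect): records of ``LM=k`` followed by
  ``k`` lines of two whitespace-separated coordinates, with optional
  ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  Reading is permissive (unknown
  keys are warned about and skipped); writing is strict.
* ESRI ASCII grids (``.asc``) carrying suitability or environmental layers
  on a regular geographic grid, lower-left origin, rows stored north-first.
* Plain CSV for the locality table and the left/right symmetry map.

Landmark indices are 1-based in files and user-facing tables, 0-based in
memory; the convention is applied at the I/O boundary only.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "SymmetryMap",
    "SuitabilityRaster",
    "read_tps",
    "write_tps",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_localities",
    "read_symmetry_map",
    "write_symmetry_map",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or fails validation."""


@dataclass
class LandmarkSet:
    """A collection of 2D landmark configurations with specimen metadata.

    Attributes
    ----------
    coords : ndarray, shape (n, k, 2)
        Landmark coordinates in a consistent (arbitrary) length unit.
    specimen_ids : list of str
    population_ids : list of str
        Population label per configuration ("" if unassigned).
    replicate_ids : list of int
        1-based digitization replicate per configuration (1 if digitized once).
    """

    coords: np.ndarray
    specimen_ids: list[str]
    population_ids: list[str] = field(default_factory=list)
    replicate_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n, k, 2)")
        n, k, _ = self.coords.shape
        if n == 0:
            raise ValueError("LandmarkSet must contain at least one configuration")
        if k < 3:
            raise ValueError(f"need at least 3 landmarks, got k={k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain missing or non-finite values")
        if len(self.specimen_ids) != n:
            raise ValueError("specimen_ids length does not match coords")
        if not self.population_ids:
            self.population_ids = [""] * n
        if not self.replicate_ids:
            self.replicate_ids = [1] * n
        if len(self.population_ids) != n or len(self.replicate_ids) != n:
            raise ValueError("metadata length does not match coords")
        keys = list(zip(self.specimen_ids, self.replicate_ids))
        if len(set(keys)) != n:
            raise ValueError("(specimen_id, replicate_id) pairs must be unique")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def subset(self, idx: Sequence[int]) -> "LandmarkSet":
        idx = list(idx)
        return LandmarkSet(
            self.coords[idx],
            [self.specimen_ids[i] for i in idx],
            [self.population_ids[i] for i in idx],
            [self.replicate_ids[i] for i in idx],
        )


@dataclass(frozen=True)
class SymmetryMap:
    """Left/right landmark pairing for object symmetry.

    ``pairs`` holds 0-based ``(left, right)`` index tuples; ``midline`` the
    unpaired indices lying on the symmetry axis.  Reflection is across the
    vertical (x-negating) axis after centering.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs))
        object.__setattr__(self, "midline", tuple(int(i) for i in self.midline))
        seen: list[int] = []
        for left, right in self.pairs:
            seen.extend((left, right))
        seen.extend(self.midline)
        k = self.k
        if sorted(seen) != list(range(k)):
            raise ValueError("pairs and midline must partition landmark indices 0..k-1 exactly")

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_midline(self) -> int:
        return len(self.midline)

    def permutation(self) -> np.ndarray:
        """Row permutation applied after the x-flip: swaps each left/right pair."""
        perm = np.arange(self.k)
        for left, right in self.pairs:
            perm[left], perm[right] = right, left
        return perm


@dataclass
class SuitabilityRaster:
    """A regular geographic grid of values, rows stored north-first.

    ``origin`` is the (longitude, latitude) of the lower-left corner of the
    grid; ``cell_size`` is in decimal degrees.  Cells equal to ``nodata``
    are missing.  For a suitability surface, valid cells lie in [0, 1].
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        return ~np.isclose(self.values, self.nodata)

    def validate_unit_interval(self) -> None:
        valid = self.values[self.mask()]
        if valid.size and (valid.min() < 0.0 or valid.max() > 1.0):
            raise FormatError("suitability values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# TPS

_TPS_KEY = re.compile(r"^([A-Z]+)\s*=\s*(.*)$")


def read_tps(path: str | Path) -> LandmarkSet:
    """Read a TPS landmark file (TpsDig2 dialect).

    One configuration per ``LM=`` record; ``SCALE=`` multiplies coordinates;
    the specimen id comes from ``ID=``, else ``IMAGE=``, else the record
    ordinal.  Unknown keys are skipped with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _TPS_KEY.match(line)
        if m:
            key, value = m.group(1), m.group(2).strip()
            if key == "LM":
                current = {"lm": int(value), "coords": [], "line": lineno}
                records.append(current)
            elif current is None:
                raise FormatError(f"{path}:{lineno}: '{key}=' before any LM= record")
            elif key in ("ID", "IMAGE", "SCALE"):
                current[key.lower()] = value
            else:
                logger.warning("%s:%d: ignoring unknown TPS key %s=", path, lineno, key)
        else:
            if current is None:
                raise FormatError(f"{path}:{lineno}: coordinates before any LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two coordinates, got {line!r}")
            current["coords"].append((float(parts[0]), float(parts[1])))

    if not records:
        raise FormatError(f"{path}: no LM= records found")

    coords_list, ids = [], []
    for ordinal, rec in enumerate(records, start=1):
        got = len(rec["coords"])
        if got != rec["lm"]:
            raise FormatError(
                f"{path}: record starting at line {rec['line']} declares LM={rec['lm']} "
                f"but has {got} coordinate lines"
            )
        if rec["lm"] == 0:
            raise FormatError(f"{path}: record at line {rec['line']} has LM=0")
        arr = np.array(rec["coords"], dtype=float)
        if "scale" in rec:
            arr = arr * float(rec["scale"])
        coords_list.append(arr)
        ids.append(rec.get("id") or rec.get("image") or str(ordinal))

    ks = {a.shape[0] for a in coords_list}
    if len(ks) != 1:
        raise FormatError(f"{path}: inconsistent landmark count across records: {sorted(ks)}")
    return LandmarkSet(np.stack(coords_list), ids)


def write_tps(lm_set: LandmarkSet, path: str | Path) -> None:
    """Write a LandmarkSet as a TPS file; round-trips through :func:`read_tps`."""
    if lm_set.n == 0:  # pragma: no cover - LandmarkSet forbids this already
        raise ValueError("nothing to write")
    buf = io.StringIO()
    for i in range(lm_set.n):
        buf.write(f"LM={lm_set.k}\n")
        for x, y in lm_set.coords[i]:
            buf.write(f"{x:.10g} {y:.10g}\n")
        buf.write(f"ID={lm_set.specimen_ids[i]}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, unit_interval: bool = True) -> SuitabilityRaster:
    """Read an ESRI ASCII grid.

    The header supplies ``ncols, nrows, xllcorner, yllcorner, cellsize`` and
    optionally ``NODATA_value``; data rows follow north-first.  With
    ``unit_interval`` (the default for suitability surfaces) non-sentinel
    values are validated into [0, 1].
    """
    path = Path(path)
    tokens = path.read_text().split()
    header: dict[str, float] = {}
    pos = 0
    while pos + 1 < len(tokens):
        key = tokens[pos].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            try:
                header[key] = float(tokens[pos + 1])
            except ValueError as exc:
                raise FormatError(f"{path}: bad header value for {key}") from exc
            pos += 2
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: malformed header, missing {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if nrows <= 0 or ncols <= 0:
        raise FormatError(f"{path}: grid dimensions must be positive")
    data = tokens[pos:]
    if len(data) != nrows * ncols:
        raise FormatError(f"{path}: expected {nrows * ncols} values, found {len(data)}")
    values = np.array(data, dtype=float).reshape(nrows, ncols)
    raster = SuitabilityRaster(
        values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=header.get("nodata_value", -9999.0),
    )
    if unit_interval:
        raster.validate_unit_interval()
    return raster


def write_ascii_grid(raster: SuitabilityRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid; round-trips exactly through :func:`read_ascii_grid`."""
    buf = io.StringIO()
    buf.write(f"ncols {raster.ncols}\n")
    buf.write(f"nrows {raster.nrows}\n")
    buf.write(f"xllcorner {raster.origin[0]:.10g}\n")
    buf.write(f"yllcorner {raster.origin[1]:.10g}\n")
    buf.write(f"cellsize {raster.cell_size:.10g}\n")
    buf.write(f"NODATA_value {raster.nodata:.10g}\n")
    for row in raster.values:
        buf.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Locality table and symmetry map

def read_localities(path: str | Path) -> pd.DataFrame:
    """Read a locality CSV with columns population_id, latitude, longitude.

    Returns a DataFrame in file order with population_id as plain strings.
    """
    df = pd.read_csv(path, dtype={"population_id": str})
    required = {"population_id", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"locality table missing columns: {sorted(missing)}")
    if df["population_id"].duplicated().any():
        dup = df.loc[df["population_id"].duplicated(), "population_id"].iloc[0]
        raise FormatError(f"duplicate population_id {dup!r}")
    if not df["latitude"].between(-90, 90).all():
        raise FormatError("latitude outside [-90, 90]")
    if not df["longitude"].between(-180, 180).all():
        raise FormatError("longitude outside [-180, 180]")
    return df.reset_index(drop=True)


def read_symmetry_map(path: str | Path) -> SymmetryMap:
    """Read a symmetry-map CSV with columns landmark, role, partner.

    Landmark indices are 1-based in the file; ``role`` is left/right/midline
    and ``partner`` names the opposite member of each pair.  The left/right
    rows must describe each pair consistently from both sides.
    """
    df = pd.read_csv(path)
    required = {"landmark", "role", "partner"}
    if required - set(df.columns):
        raise FormatError(f"symmetry map must have columns {sorted(required)}")
    pairs: dict[int, int] = {}
    midline: list[int] = []
    partner_of: dict[int, int] = {}
    for _, row in df.iterrows():
        lm = int(row["landmark"]) - 1
        role = str(row["role"]).strip().lower()
        if role == "midline":
            midline.append(lm)
        elif role in ("left", "right"):
            partner = int(row["partner"]) - 1
            partner_of[lm] = partner
            if role == "left":
                pairs[lm] = partner
        else:
            raise FormatError(f"unknown role {row['role']!r} for landmark {lm + 1}")
    for lm, partner in partner_of.items():
        if partner_of.get(partner) != lm:
            raise FormatError(
                f"inconsistent pairing: landmark {lm + 1} names {partner + 1} "
                "but is not named back"
            )
    return SymmetryMap(tuple(sorted(pairs.items())), tuple(sorted(midline)))


def write_symmetry_map(sym: SymmetryMap, path: str | Path) -> None:
    rows = []
    for left, right in sym.pairs:
        rows.append({"landmark": left + 1, "role": "left", "partner": right + 1})
        rows.append({"landmark": right + 1, "role": "right", "partner": left + 1})
    for lm in sym.midline:
        rows.append({"landmark": lm + 1, "role": "midline", "partner": ""})
    pd.DataFrame(rows).sort_values("landmark").to_csv(path, index=False)
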