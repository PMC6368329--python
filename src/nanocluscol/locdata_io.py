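"""Localization-table and ROI input/output.

SMLM detectors emit one row per localization (a single fluorophore blink
fitted to sub-pixel precision). This module reads those tab-delimited
tables into :class:`LocalizationTable`, reads/writes polygon regions of
interest (ROIs), restricts tables to an ROI, and round-trips cluster
tables produced downstream.

Coordinates are Cartesian nanometres with y increasing upward; no
image-axis flip is applied. Point-in-polygon tests are
boundary-inclusive so localizations hugging the ROI outline are kept.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "LocalizationTable",
    "RoiPolygon",
    "Dialect",
    "read_localizations",
    "read_roi",
    "write_roi",
    "filter_by_roi",
    "write_cluster_table",
    "read_cluster_table",
    "CLUSTER_TABLE_COLUMNS",
]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalizationTable:
    """Per-localization records: id, x (nm), y (nm), channel, frame.

    ``channels`` is the declared channel set (at most two names for the
    two-colour experiments this package targets); every record's channel
    must be a member.
    """

    df: pd.DataFrame
    channels: tuple[str, ...]

    def __post_init__(self):
        required = {"id", "x", "y", "channel", "frame"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"localization table lacks columns: {sorted(missing)}")
        if len(self.channels) > 2:
            raise ValidationError("at most two channels are supported")
        xy = self.df[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("non-finite coordinates in localization table")
        if self.df["id"].duplicated().any():
            raise ValidationError("duplicated localization ids")
        bad = set(self.df["channel"]) - set(self.channels)
        if bad:
            raise ValidationError(f"records with undeclared channel(s): {sorted(bad)}")
        if (self.df["frame"].to_numpy() < 0).any():
            raise ValidationError("negative frame numbers")

    def __len__(self) -> int:
        return len(self.df)

    def coords(self, channel: str | None = None) -> np.ndarray:
        """(n, 2) float array of x/y, optionally restricted to one channel."""
        df = self.df if channel is None else self.df[self.df["channel"] == channel]
        return df[["x", "y"]].to_numpy(float)

    def ids(self, channel: str | None = None) -> np.ndarray:
        df = self.df if channel is None else self.df[self.df["channel"] == channel]
        return df["id"].to_numpy()

    def select_channel(self, channel: str) -> "LocalizationTable":
        if channel not in self.channels:
            raise ValidationError(f"unknown channel {channel!r}")
        return LocalizationTable(
            self.df[self.df["channel"] == channel].reset_index(drop=True),
            self.channels,
        )


@dataclass(frozen=True)
class RoiPolygon:
    """Simple polygon (vertices in nm, implicit closure) bounding the analysis region."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("ROI polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite ROI vertex")
        object.__setattr__(self, "vertices", v)
        poly = shapely.Polygon(v)
        if not poly.is_valid:
            raise ValidationError("self-intersecting ROI polygon")
        if poly.area <= 0:
            raise ValidationError("ROI polygon has zero area")
        object.__setattr__(self, "_poly", poly)

    @property
    def polygon(self) -> shapely.Polygon:
        return self._poly  # type: ignore[attr-defined]

    @property
    def area(self) -> float:
        return self.polygon.area

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership mask for an (n, 2) array."""
        xy = np.asarray(xy, float)
        if xy.size == 0:
            return np.zeros(0, dtype=bool)
        return shapely.covers(self.polygon, shapely.points(xy))

    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds


# ---------------------------------------------------------------------------
# Localization-table reading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """Column mapping for a tab-delimited localization export.

    Acquisition software (e.g. NIS Elements) varies its column schema
    between versions, so the mapping is explicit: ``x``/``y`` name the
    coordinate columns, ``scale`` converts them to nm (1000 for µm
    exports), ``channel`` may be a column name or None with
    ``default_channel`` supplying a constant label, and ``frame``
    likewise defaults to 0 when absent.
    """

    x: str = "X"
    y: str = "Y"
    channel: str | None = "Channel"
    frame: str | None = "Frame"
    scale: float = 1.0
    default_channel: str = "ch0"
    delimiter: str = "\t"


def read_localizations(
    path: str | Path,
    dialect: Dialect = Dialect(),
    channels: Sequence[str] | None = None,
) -> LocalizationTable:
    """Read a delimited localization table.

    ``channels`` optionally declares the channel set; by default the
    distinct labels found in the file are used (sorted).

    Raises :class:`FormatError` when a mapped column is missing and
    :class:`ParseError` (with the 1-based file line number) when a
    coordinate fails to parse as a finite number.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    for col in (dialect.x, dialect.y):
        if col not in raw.columns:
            raise FormatError(f"{path.name}: mapped column {col!r} not found "
                              f"(have {list(raw.columns)})")
    for col in (dialect.channel, dialect.frame):
        if col is not None and col not in raw.columns:
            raise FormatError(f"{path.name}: mapped column {col!r} not found")

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            line = row + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path.name}: non-numeric value {raw[col].iloc[row]!r} in column "
                f"{col!r} at line {line}", line=line)
        return vals

    x = _numeric(dialect.x) * dialect.scale
    y = _numeric(dialect.y) * dialect.scale
    if dialect.channel is not None:
        channel = raw[dialect.channel].astype(str).to_numpy()
    else:
        channel = np.full(len(raw), dialect.default_channel, dtype=object)
    if dialect.frame is not None:
        frame = pd.to_numeric(raw[dialect.frame], errors="coerce")
        if frame.isna().any():
            row = int(np.flatnonzero(frame.isna().to_numpy())[0])
            raise ParseError(f"{path.name}: non-numeric frame at line {row + 2}",
                             line=row + 2)
        frame = frame.astype(int).to_numpy()
    else:
        frame = np.zeros(len(raw), dtype=int)

    df = pd.DataFrame({
        "id": np.arange(len(raw)),
        "x": x,
        "y": y,
        "channel": channel,
        "frame": frame,
    })
    declared = tuple(channels) if channels is not None else tuple(sorted(set(channel)))
    return LocalizationTable(df, declared)


def write_localizations(table: LocalizationTable, path: str | Path,
                        dialect: Dialect = Dialect()) -> None:
    """Write a table in the same dialect the reader accepts (scale reversed)."""
    out = pd.DataFrame({
        dialect.x: table.df["x"] / dialect.scale,
        dialect.y: table.df["y"] / dialect.scale,
    })
    if dialect.channel is not None:
        out[dialect.channel] = table.df["channel"]
    if dialect.frame is not None:
        out[dialect.frame] = table.df["frame"]
    out.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# ROI files: one "x<TAB>y" vertex per line, nm
# ---------------------------------------------------------------------------

def read_roi(path: str | Path) -> RoiPolygon:
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path.name}: expected 'x<TAB>y' at line {lineno}",
                             line=lineno)
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ParseError(f"{path.name}: non-numeric vertex at line {lineno}",
                             line=lineno) from exc
    return RoiPolygon(np.asarray(rows, float))


def write_roi(roi: RoiPolygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        for x, y in roi.vertices:
            fh.write(f"{x:.6f}\t{y:.6f}\n")


def filter_by_roi(table: LocalizationTable, roi: RoiPolygon) -> LocalizationTable:
    """Keep records inside or on the boundary of the ROI; ids are preserved."""
    mask = roi.contains_points(table.coords())
    return LocalizationTable(table.df[mask].reset_index(drop=True), table.channels)


# ---------------------------------------------------------------------------
# Cluster tables
# ---------------------------------------------------------------------------

CLUSTER_TABLE_COLUMNS = [
    "id", "channel", "n_locs", "n_interacting", "interaction_class",
    "area_nm2", "density_per_nm2", "relative_density",
]


def write_cluster_table(clusters: Sequence, path: str | Path) -> None:
    """One CSV row per cluster; floats carry >= 10 significant digits so the
    matching reader round-trips within 1e-6 relative."""
    rows = []
    for c in clusters:
        rows.append({
            "id": c.cluster_id,
            "channel": c.channel,
            "n_locs": c.n_locs,
            "n_interacting": c.n_interacting,
            "interaction_class": c.interaction_class,
            "area_nm2": c.area,
            "density_per_nm2": c.density,
            "relative_density": c.relative_density,
        })
    pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLUSTER_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"cluster table lacks columns: {sorted(missing)}")
    return df
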