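"""Reading and writing fix tables, and ground-elevation attachment.

A *fix table* is a :class:`pandas.DataFrame` with one row per GPS record and
the canonical columns ``animal_id, t, x, y, z, kph, hdop, vdop, fix_dim``
(plus optional ``ground_elev, age_class, stage``).  ``t`` is a timezone-aware
UTC timestamp; ``x``/``y`` are projected coordinates in meters (e.g. UTM) —
the package never works in unprojected degrees.

Ground elevation can come from a constant, a pre-existing column, or a
plain-text ESRI ASCII grid (:class:`AsciiGrid`) sampled nearest-cell, which
matches the native resolution of the ~30 m terrain models typically used
with raptor telemetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MANDATORY_COLUMNS, OPTIONAL_COLUMNS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


@dataclass
class AsciiGrid:
    """Minimal in-memory ESRI ASCII elevation grid.

    Row 0 of ``values`` is the northernmost row, as in the .asc format.
    Coordinates must share the fixes' projected CRS; the format carries no
    CRS metadata, so consistency is the caller's responsibility.
    """

    values: np.ndarray  # (nrows, ncols), north to south
    xll: float  # x of lower-left corner
    yll: float  # y of lower-left corner
    cellsize: float
    nodata: float | None = None

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        header: dict[str, float] = {}
        rows: list[np.ndarray] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append(np.asarray(parts, dtype=float))
        values = np.vstack(rows)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid data shape does not match header")
        return cls(
            values=values,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value"),
        )

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell elevation at projected (x, y); NaN outside extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrows, ncols = self.values.shape
        col = np.floor((x - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cellsize).astype(int)
        row = nrows - 1 - row_from_bottom
        out = np.full(x.shape, np.nan)
        ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        vals = self.values[row[ok], col[ok]]
        if self.nodata is not None:
            vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out


def read_fixes(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited fix table into canonical form.

    Parameters
    ----------
    path
        CSV file with one row per GPS fix.
    column_map
        Mapping from canonical name (e.g. ``"animal_id"``) to the column
        name used in the file.  Unmapped canonical names are assumed to
        appear verbatim.

    Returns
    -------
    DataFrame sorted by ``(animal_id, t)`` with exact duplicate
    ``(animal_id, t)`` rows collapsed to the first occurrence and rows with
    unparseable mandatory fields dropped.  The counts of both removals are
    logged and stored in ``df.attrs["n_duplicates"]`` / ``attrs["n_bad_rows"]``.
    """
    raw = pd.read_csv(path)
    if raw.empty and raw.columns.empty:
        logger.warning("read_fixes: %s is empty", path)
    column_map = column_map or {}
    rename = {src: canon for canon, src in column_map.items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    keep = [c for c in (*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS) if c in raw.columns]
    df = raw[keep].copy()

    df["t"] = pd.to_datetime(df["t"], utc=True, errors="coerce", format="mixed")
    for col in ("x", "y", "z", "kph", "hdop", "vdop"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "ground_elev" in df.columns:
        df["ground_elev"] = pd.to_numeric(df["ground_elev"], errors="coerce")
    df["animal_id"] = df["animal_id"].astype(str)
    df["fix_dim"] = df["fix_dim"].astype(str).str.upper()

    bad = df[["animal_id", "t", "x", "y", "z", "kph", "hdop", "vdop"]].isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("read_fixes: dropped %d row(s) with unparseable fields", n_bad)
    df = df.loc[~bad]

    df = df.sort_values(["animal_id", "t"], kind="stable")
    dup = df.duplicated(subset=["animal_id", "t"], keep="first")
    n_dup = int(dup.sum())
    if n_dup:
        logger.warning("read_fixes: collapsed %d duplicate (animal, t) row(s)", n_dup)
    df = df.loc[~dup].reset_index(drop=True)
    df.attrs["n_duplicates"] = n_dup
    df.attrs["n_bad_rows"] = n_bad
    return df


def attach_ground_elevation(fixes: pd.DataFrame, dem) -> pd.DataFrame:
    """Return a copy of ``fixes`` with ``ground_elev`` set from ``dem``.

    ``dem`` may be a scalar elevation (m), an :class:`AsciiGrid`, or a path
    to an ESRI ASCII grid file.  Fixes outside a grid's extent get missing
    ground elevation (they are later excluded when AGL is needed).
    """
    out = fixes.copy()
    if np.isscalar(dem):
        out["ground_elev"] = float(dem)
        return out
    if isinstance(dem, (str, Path)):
        dem = AsciiGrid.read(dem)
    if not isinstance(dem, AsciiGrid):
        raise TypeError("dem must be a scalar, AsciiGrid, or path to an .asc file")
    out["ground_elev"] = dem.sample(out["x"].to_numpy(), out["y"].to_numpy())
    n_out = int(out["ground_elev"].isna().sum())
    if n_out:
        logger.warning(
            "attach_ground_elevation: %d fix(es) outside raster extent", n_out
        )
    return out


def write_classified(
    path,
    fixes: pd.DataFrame,
    features: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    behaviors: pd.Series | None = None,
    segment_ids: pd.Series | None = None,
    subsegment_ids: pd.Series | None = None,
) -> pd.DataFrame:
    """Write one row per input fix with classification columns appended.

    ``features``/``labels``/... must be indexed like ``fixes`` (or be None);
    fixes filtered out upstream simply have empty cells in the appended
    columns.  Raises on any length/index mismatch.  Returns the frame that
    was written.
    """
    out = fixes.copy()
    extras = {
        "cluster": labels,
        "behavior": behaviors,
        "segment_id": segment_ids,
        "subsegment_id": subsegment_ids,
    }
    if features is not None:
        if len(features) != len(fixes) and not features.index.isin(fixes.index).all():
            raise ValueError("features index does not align with fixes")
        for col in features.columns:
            out[col] = features[col]
    for name, series in extras.items():
        if series is None:
            continue
        series = pd.Series(series)
        if len(series) != len(fixes) and not series.index.isin(fixes.index).all():
            raise ValueError(f"{name} does not align with fixes")
        out[name] = series
    ts = out["t"]
    out = out.assign(t=ts.dt.strftime("%Y-%m-%dT%H:%M:%S%z"))
    out.to_csv(path, index=False)
    return out
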