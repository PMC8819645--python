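"""The six focal movement variables and their transform for clustering.

Each GPS fix is described by:

* ``kph`` — instantaneous speed reported by the biologger (km/h);
* ``sn`` — step speed: horizontal displacement over elapsed time (m/s);
* ``agl`` — altitude above ground level: GPS altitude minus terrain (m);
* ``abs_angle`` — absolute turn angle over three sequential fixes (rad);
* ``vr`` — vertical rate: altitude change over elapsed time (m/s);
* ``abs_vr`` — absolute vertical rate (m/s).

Difference-based variables are backward looking: the value at fix *i* uses
fixes *i−1* (and *i−2* for the turn angle) of the same animal, and is
missing when there is no predecessor, when the interval exceeds ``max_gap``
(so all derived variables are measured over comparable time spans), or when
a displacement has zero length (turn angle undefined).

Before clustering, right-skewed variables are square-root transformed and
every variable is centered and scaled to unit variance so the Euclidean
metric is not dominated by large-variance attributes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_SQRT_FLAGS, FOCAL_VARIABLES


def turn_angle(p1, p2, p3) -> float:
    """Absolute change of bearing from step p1→p2 to step p2→p3, in [0, π].

    Returns NaN if either step has zero length (the turn is undefined).
    """
    x1, y1 = p1
    x2, y2 = p2
    x3, y3 = p3
    if (x1 == x2 and y1 == y2) or (x2 == x3 and y2 == y3):
        return float("nan")
    b1 = math.atan2(y2 - y1, x2 - x1)
    b2 = math.atan2(y3 - y2, x3 - x2)
    d = b2 - b1
    # wrap to (-pi, pi] before taking the absolute value
    if d <= -math.pi:
        d += 2.0 * math.pi
    elif d > math.pi:
        d -= 2.0 * math.pi
    return abs(d)


def _epoch_seconds(t: pd.Series) -> np.ndarray:
    return t.astype("int64").to_numpy() / 1e9


def compute_focal_variables(fixes: pd.DataFrame, max_gap: float = 11.0) -> pd.DataFrame:
    """Compute the six focal variables for every fix.

    ``fixes`` must be time-ordered within each animal (as produced by
    :func:`flightmodes.io.read_fixes`).  Returns a DataFrame indexed like
    ``fixes`` with columns ``kph, sn, agl, abs_angle, vr, abs_vr``; missing
    values are NaN.

    Raises
    ------
    ValueError
        If two consecutive retained fixes of one animal share a timestamp
        or are out of order (duplicates must be collapsed upstream).
    """
    n = len(fixes)
    out = pd.DataFrame(
        np.nan, index=fixes.index, columns=list(FOCAL_VARIABLES), dtype=float
    )
    if n == 0:
        return out

    out["kph"] = fixes["kph"].to_numpy(dtype=float)
    if "ground_elev" in fixes.columns:
        out["agl"] = fixes["z"].to_numpy(dtype=float) - fixes["ground_elev"].to_numpy(
            dtype=float
        )

    t = _epoch_seconds(fixes["t"])
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    z = fixes["z"].to_numpy(dtype=float)
    same_animal = np.zeros(n, dtype=bool)
    same_animal[1:] = (
        fixes["animal_id"].to_numpy()[1:] == fixes["animal_id"].to_numpy()[:-1]
    )

    dt = np.full(n, np.nan)
    dt[1:] = t[1:] - t[:-1]
    if np.any(same_animal & (dt <= 0)):
        raise ValueError(
            "non-increasing timestamps within an animal; collapse duplicates first"
        )

    dx = np.full(n, np.nan)
    dy = np.full(n, np.nan)
    dz = np.full(n, np.nan)
    dx[1:] = x[1:] - x[:-1]
    dy[1:] = y[1:] - y[:-1]
    dz[1:] = z[1:] - z[:-1]

    valid_step = same_animal & (dt > 0) & (dt <= max_gap)
    dist = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        sn = np.where(valid_step, dist / dt, np.nan)
        vr = np.where(valid_step, dz / dt, np.nan)
    out["sn"] = sn
    out["vr"] = vr
    out["abs_vr"] = np.abs(vr)

    # turn angle at i needs steps (i-1 -> i) and (i-2 -> i-1), both valid
    # and of nonzero length
    heading = np.where(valid_step & (dist > 0), np.arctan2(dy, dx), np.nan)
    ang = np.full(n, np.nan)
    prev_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = ~np.isnan(heading[:-1]) & same_animal[:-1]
    both = ~np.isnan(heading) & prev_ok & same_animal
    d = np.full(n, np.nan)
    d[both] = heading[both] - np.roll(heading, 1)[both]
    d = np.where(d <= -np.pi, d + 2 * np.pi, d)
    d = np.where(d > np.pi, d - 2 * np.pi, d)
    ang[both] = np.abs(d[both])
    out["abs_angle"] = ang
    return out


@dataclass
class ScalingParams:
    """Square-root flags plus pooled means and SDs of the transformed variables.

    Sufficient to apply the identical transform to new data when classifying
    fixes with a saved model.  SDs use the sample (n−1) denominator.
    """

    sqrt_flags: dict
    means: dict
    sds: dict

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"standard deviation for '{name}' must be > 0")
        if tuple(self.means) != FOCAL_VARIABLES:
            self.means = {v: self.means[v] for v in FOCAL_VARIABLES}
            self.sds = {v: self.sds[v] for v in FOCAL_VARIABLES}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def destandardize(self, centroids: np.ndarray) -> pd.DataFrame:
        """Map points in standardized space back to the original scale.

        Inverts the centering/scaling and squares the square-root-flagged
        coordinates, so centroids can be read in natural units.
        """
        centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
        cols = {}
        for j, v in enumerate(FOCAL_VARIABLES):
            val = centroids[:, j] * self.sds[v] + self.means[v]
            if self.sqrt_flags[v]:
                val = np.sign(val) * val**2
            cols[v] = val
        return pd.DataFrame(cols)


def _sqrt_transform(df: pd.DataFrame, sqrt_flags: dict) -> pd.DataFrame:
    out = df.astype(float).copy()
    for v in out.columns:
        if sqrt_flags.get(v, False):
            # small negative AGL (DEM error near ground) is clamped to 0
            out[v] = np.sqrt(np.clip(out[v].to_numpy(), 0.0, None))
    return out


def fit_transform(
    features: pd.DataFrame, sqrt_flags: dict | None = None
) -> tuple[pd.DataFrame, ScalingParams]:
    """Square-root transform, center and scale the focal-variable matrix.

    Means and SDs are pooled across all retained fixes of all animals.
    Raises on missing values (the second-tier filter must run first) and on
    zero-variance columns.
    """
    missing_cols = [v for v in FOCAL_VARIABLES if v not in features.columns]
    if missing_cols:
        raise ValueError(f"missing focal variable(s): {missing_cols}")
    features = features[list(FOCAL_VARIABLES)]
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ValueError(f"missing values present in {bad}; apply second-tier filter")
    sqrt_flags = dict(DEFAULT_SQRT_FLAGS if sqrt_flags is None else sqrt_flags)

    transformed = _sqrt_transform(features, sqrt_flags)
    means = transformed.mean()
    sds = transformed.std(ddof=1)
    # relative tolerance: a column constant up to rounding carries no signal
    floor = 1e-12 * (means.abs() + 1.0)
    zero = sds[~(sds > floor)].index.tolist()
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    std = (transformed - means) / sds
    params = ScalingParams(
        sqrt_flags=sqrt_flags, means=means.to_dict(), sds=sds.to_dict()
    )
    return std, params


def apply_transform(features: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Apply a previously fitted transform to new data (not idempotent)."""
    missing_cols = [v for v in FOCAL_VARIABLES if v not in features.columns]
    if missing_cols:
        raise ValueError(f"missing focal variable(s): {missing_cols}")
    features = features[list(FOCAL_VARIABLES)]
    transformed = _sqrt_transform(features, params.sqrt_flags)
    return (transformed - pd.Series(params.means)) / pd.Series(params.sds)
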