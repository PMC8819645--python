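"""Run configuration for the classification pipeline.

All thresholds of the two-tier quality filter, the clustering run, and the
K-selection bootstrap live in one :class:`RunConfig` so that a run is fully
described by (data, config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Canonical order of the six focal movement variables used in clustering.
FOCAL_VARIABLES = ("kph", "sn", "agl", "abs_angle", "vr", "abs_vr")

#: Variables that receive a square-root transform before standardization.
#: Vertical rate (vr) is signed and roughly symmetric, so it is left alone.
DEFAULT_SQRT_FLAGS = {
    "kph": True,
    "sn": True,
    "agl": True,
    "abs_angle": True,
    "vr": False,
    "abs_vr": True,
}

#: Mandatory columns of a fix table.
MANDATORY_COLUMNS = ("animal_id", "t", "x", "y", "z", "kph", "hdop", "vdop", "fix_dim")

#: Optional columns carried through when present.
OPTIONAL_COLUMNS = ("ground_elev", "age_class", "stage")


@dataclass
class RunConfig:
    """Thresholds and sizes controlling a full classification run.

    Parameters
    ----------
    hdop_max, vdop_max
        Dilution-of-precision ceilings; fixes with HDOP or VDOP strictly
        greater than these are removed (first tier).
    agl_min
        Minimum plausible altitude above ground (m); fixes below are removed.
    max_gap
        Maximum inter-fix interval (s) within a segment; larger gaps split
        tracks and invalidate difference-based features.
    min_segment_points
        Minimum number of consecutive fixes for a segment to be retained.
    k_range
        Candidate cluster counts examined during K selection.
    n_starts
        Random restarts per K-means fit.
    n_boot_replicates
        Number of bootstrap replicates (B) for the silhouette curve.
    boot_sample_size
        Size of each bootstrap resample (n_boot).
    max_iter
        Lloyd-iteration cap per K-means start.
    seed
        Master seed; every random draw in the pipeline descends from it.
    max_speed_kph, max_agl
        Optional rule-based anomaly caps applied in the first tier
        (disabled by default).
    """

    hdop_max: float = 10.0
    vdop_max: float = 10.0
    agl_min: float = -50.0
    max_gap: float = 11.0
    min_segment_points: int = 3
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    n_starts: int = 10
    n_boot_replicates: int = 1000
    boot_sample_size: int = 10000
    max_iter: int = 100
    seed: int = 0
    max_speed_kph: float | None = None
    max_agl: float | None = None

    def __post_init__(self) -> None:
        if not self.max_gap > 0:
            raise ValueError("max_gap must be positive")
        if self.min_segment_points < 3:
            raise ValueError("min_segment_points must be >= 3")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        self.k_range = tuple(int(k) for k in self.k_range)
        for name in ("hdop_max", "vdop_max", "agl_min", "max_gap"):
            v = float(getattr(self, name))
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
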