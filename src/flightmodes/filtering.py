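"""Two-tier quality filtering of GPS fix tables.

First tier removes fixes whose diagnostics indicate low precision
(HDOP/VDOP above threshold, 2-D fixes, implausibly low altitude above
ground), optionally followed by rule-based anomaly caps on speed and AGL.
Second tier removes fixes with missing focal variables, splits each
animal's remaining sequence wherever consecutive fixes are more than
``max_gap`` seconds apart, and drops the resulting runs shorter than
``min_segment_points`` fixes.  Each rule's removal count is reported.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FOCAL_VARIABLES, RunConfig

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-rule removal counts for one filtering pass.

    ``n_input == n_retained + sum(removed.values())``; each removed fix is
    attributed to the first rule it violates, so per-rule counts depend on
    rule order but the total retained does not.
    """

    n_input: int
    removed: dict = field(default_factory=dict)
    n_retained: int = 0
    n_segments: int | None = None
    segment_points: dict | None = None  # min/median/max points per segment
    segment_seconds: dict | None = None  # min/median/max duration per segment

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.removed.values()):
            raise ValueError("filter report counts are inconsistent")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def __str__(self) -> str:
        lines = [f"input fixes:    {self.n_input}"]
        for rule, n in self.removed.items():
            lines.append(f"removed by {rule}: {n}")
        lines.append(f"retained fixes: {self.n_retained}")
        if self.n_segments is not None:
            lines.append(f"segments:       {self.n_segments}")
            if self.segment_points:
                sp, ss = self.segment_points, self.segment_seconds
                lines.append(
                    f"segment length: {sp['min']}-{sp['max']} points "
                    f"(median {sp['median']}), "
                    f"{ss['min']:.0f}-{ss['max']:.0f} s (median {ss['median']:.0f})"
                )
        return "\n".join(lines)


def first_tier_filter(
    fixes: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove low-precision fixes; thresholds are strict inequalities.

    Rules, in order: HDOP or VDOP strictly above the maxima; 2-D fix;
    AGL below ``agl_min``; then the optional speed/AGL anomaly caps.
    A fix with HDOP exactly at the threshold is retained.  If ground
    elevation is absent the AGL rules are skipped with a warning.
    """
    config = config or RunConfig()
    n = len(fixes)
    removed: dict[str, int] = {}
    alive = np.ones(n, dtype=bool)

    def apply(rule: str, viol: np.ndarray) -> None:
        hit = alive & np.asarray(viol, dtype=bool)
        removed[rule] = int(hit.sum())
        alive[hit] = False

    hdop = fixes["hdop"].to_numpy(dtype=float)
    vdop = fixes["vdop"].to_numpy(dtype=float)
    apply("hdop_vdop", (hdop > config.hdop_max) | (vdop > config.vdop_max))
    apply("fix_2d", fixes["fix_dim"].astype(str).str.upper().to_numpy() == "2D")

    have_ground = "ground_elev" in fixes.columns and fixes["ground_elev"].notna().any()
    if have_ground:
        agl = fixes["z"].to_numpy(dtype=float) - fixes["ground_elev"].to_numpy(float)
        apply("agl_low", agl < config.agl_min)
    else:
        logger.warning("first_tier_filter: no ground elevation; AGL rule skipped")

    if config.max_speed_kph is not None:
        apply("speed_cap", fixes["kph"].to_numpy(dtype=float) > config.max_speed_kph)
    if config.max_agl is not None and have_ground:
        apply("agl_cap", agl > config.max_agl)

    retained = fixes.loc[alive]
    report = FilterReport(n_input=n, removed=removed, n_retained=int(alive.sum()))
    return retained, report


def _segment_lengths(df: pd.DataFrame) -> tuple[dict, dict]:
    grp = df.groupby(["animal_id", "segment_id"], observed=True)
    pts = grp.size()
    t = df["t"].astype("int64") / 1e9
    secs = t.groupby(
        [df["animal_id"], df["segment_id"]], observed=True
    ).agg(lambda s: s.max() - s.min())
    as_summary = lambda s, cast: {
        "min": cast(s.min()), "median": float(s.median()), "max": cast(s.max())
    }
    return as_summary(pts, int), as_summary(secs, float)


def second_tier_filter(
    features: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop incomplete fixes, split at gaps, drop short runs, assign segments.

    ``features`` must carry ``animal_id`` and ``t`` alongside the six focal
    variables (as assembled by the model facade).  Gap evaluation uses the
    timestamps remaining *after* the missing-value drop, which is the
    conservative reading of the cascade: removing a fix widens the gap its
    neighbours must survive.

    Returns the retained rows with an integer ``segment_id`` column
    (consecutive per animal, starting at 0) and a :class:`FilterReport`
    including segment counts and length summaries.
    """
    config = config or RunConfig()
    n = len(features)
    missing = features[list(FOCAL_VARIABLES)].isna().any(axis=1)
    complete = features.loc[~missing].copy()

    if complete.empty:
        report = FilterReport(
            n_input=n,
            removed={"missing_values": int(missing.sum()), "short_segment": 0},
            n_retained=0,
            n_segments=0,
        )
        complete["segment_id"] = pd.Series(dtype=int)
        return complete, report

    t = complete["t"].astype("int64").to_numpy() / 1e9
    animal = complete["animal_id"].to_numpy()
    new_animal = np.ones(len(complete), dtype=bool)
    new_animal[1:] = animal[1:] != animal[:-1]
    gap = np.ones(len(complete), dtype=bool)
    gap[1:] = (t[1:] - t[:-1]) > config.max_gap
    run_start = new_animal | gap
    run_id = np.cumsum(run_start) - 1

    sizes = np.bincount(run_id)
    keep = sizes[run_id] >= config.min_segment_points
    n_short = int((~keep).sum())
    retained = complete.loc[keep].copy()
    kept_runs = run_id[keep]

    # consecutive ids per animal
    seg = np.zeros(len(retained), dtype=int)
    if len(retained):
        animal_r = retained["animal_id"].to_numpy()
        new_a = np.ones(len(retained), dtype=bool)
        new_a[1:] = animal_r[1:] != animal_r[:-1]
        new_run = np.ones(len(retained), dtype=bool)
        new_run[1:] = kept_runs[1:] != kept_runs[:-1]
        counter = np.cumsum(new_run | new_a)
        first_of_animal = np.where(new_a)[0]
        base = np.zeros(len(retained), dtype=int)
        base[first_of_animal] = counter[first_of_animal]
        base = np.maximum.accumulate(base)
        seg = counter - base
    retained["segment_id"] = seg

    n_segments = int(retained.groupby("animal_id", observed=True)["segment_id"]
                     .nunique().sum()) if len(retained) else 0
    seg_pts, seg_secs = (
        _segment_lengths(retained) if len(retained) else (None, None)
    )
    report = FilterReport(
        n_input=n,
        removed={"missing_values": int(missing.sum()), "short_segment": n_short},
        n_retained=len(retained),
        n_segments=n_segments,
        segment_points=seg_pts,
        segment_seconds=seg_secs,
    )
    return retained, report
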