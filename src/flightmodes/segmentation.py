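"""Behavioral interpretation: labels, subsegments, transitions, summaries.

A *behavioral subsegment* is a maximal run of consecutive fixes within one
segment (so every internal gap is below the segment threshold) that all
carry the same cluster.  Single-point subsegments are legitimate and have
duration 0 s.  Transitions between consecutive subsegments — with the end
of a segment as an absorbing pseudo-state — summarize behavioral
sequentiality as a row-stochastic matrix with a structurally zero diagonal.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import KMeansResult
from .config import FOCAL_VARIABLES

#: Column label of the end-of-segment pseudo-state in transition matrices.
SEGMENT_END = "segment_end"

BEHAVIOR_NAMES = ("perching", "ascending", "flapping", "gliding")


class LabelingError(ValueError):
    """The automatic behavior-labeling rule is ambiguous for this model."""


def label_behaviors(model: KMeansResult) -> dict[int, str]:
    """Map cluster ids to flight-mode names from centroid attributes.

    For K = 4, centroids are de-standardized to natural units and named by
    the canonical raptor pattern: the slowest centroid (mean rank of the two
    speed variables) is *perching*; among the rest the largest vertical rate
    is *ascending*, the smallest *gliding*, and the remainder *flapping*.
    Ties raise :class:`LabelingError` (supply a manual mapping instead);
    other K get generic names with a warning.  The automatic rule is a
    convenience — expert-assigned mappings always take precedence.
    """
    if model.scaling is None:
        raise ValueError("model has no scaling parameters; cannot de-standardize")
    cents = model.scaling.destandardize(model.centroids)
    k = model.k
    if k != 4:
        warnings.warn(f"auto-labeling defined for K=4, got K={k}; generic names used")
        return {i + 1: f"cluster_{i + 1}" for i in range(k)}

    speed_rank = (
        cents["kph"].rank(method="average") + cents["sn"].rank(method="average")
    ) / 2.0
    lowest = speed_rank[speed_rank == speed_rank.min()]
    if len(lowest) > 1:
        raise LabelingError(
            "two centroids tie on speed rank; supply a manual cluster->behavior map"
        )
    perch = int(lowest.index[0])

    rest = cents.drop(index=perch)
    vr = rest["vr"]
    if (vr == vr.max()).sum() > 1 or (vr == vr.min()).sum() > 1:
        raise LabelingError(
            "centroids tie on vertical rate; supply a manual cluster->behavior map"
        )
    ascend = int(vr.idxmax())
    glide = int(vr.idxmin())
    if ascend == glide:
        raise LabelingError("vertical rates indistinguishable; supply a manual map")
    flap = int(rest.index.difference([ascend, glide])[0])
    return {
        perch + 1: "perching",
        ascend + 1: "ascending",
        flap + 1: "flapping",
        glide + 1: "gliding",
    }


def find_subsegments(labeled: pd.DataFrame) -> pd.DataFrame:
    """Maximal same-cluster runs within each segment, in time order.

    ``labeled`` needs columns ``animal_id, t, segment_id, cluster`` (and
    optionally ``behavior``), time-ordered within (animal, segment).
    Returns one row per subsegment with ``n_points``, ``t_start``,
    ``t_end`` and ``duration`` in seconds (0 for a single point).
    """
    required = {"animal_id", "t", "segment_id", "cluster"}
    missing = required - set(labeled.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    if labeled["cluster"].isna().any():
        raise ValueError("unlabeled fix inside a segment")
    if labeled.empty:
        return pd.DataFrame(
            columns=[
                "animal_id", "segment_id", "subsegment_id", "cluster",
                "behavior", "n_points", "t_start", "t_end", "duration",
            ]
        )

    df = labeled
    animal = df["animal_id"].to_numpy()
    seg = df["segment_id"].to_numpy()
    clu = df["cluster"].to_numpy()
    t = df["t"].astype("int64").to_numpy() / 1e9

    new_seg = np.ones(len(df), dtype=bool)
    new_seg[1:] = (animal[1:] != animal[:-1]) | (seg[1:] != seg[:-1])
    new_run = new_seg.copy()
    new_run[1:] |= clu[1:] != clu[:-1]
    run_id = np.cumsum(new_run) - 1

    starts = np.flatnonzero(new_run)
    ends = np.r_[starts[1:] - 1, len(df) - 1]
    seg_of_run = np.cumsum(new_seg) - 1

    sub = pd.DataFrame(
        {
            "animal_id": animal[starts],
            "segment_id": seg[starts],
            "cluster": clu[starts],
            "n_points": ends - starts + 1,
            "t_start": df["t"].to_numpy()[starts],
            "t_end": df["t"].to_numpy()[ends],
            "duration": t[ends] - t[starts],
        }
    )
    # consecutive subsegment id within each segment
    seg_run = seg_of_run[starts]
    first = np.ones(len(sub), dtype=bool)
    first[1:] = seg_run[1:] != seg_run[:-1]
    counter = np.arange(len(sub))
    base = np.where(first, counter, 0)
    base = np.maximum.accumulate(base)
    sub.insert(2, "subsegment_id", counter - base)
    if "behavior" in df.columns:
        sub.insert(4, "behavior", df["behavior"].to_numpy()[starts])
    else:
        sub.insert(4, "behavior", sub["cluster"].map(lambda c: f"cluster_{c}"))
    return sub


@dataclass
class TransitionMatrix:
    """Counts and row-normalized probabilities between behaviors.

    Rows are the initial behavior; columns the subsequent behavior plus a
    terminal ``segment_end`` pseudo-state.  The diagonal is structurally
    zero because subsegments are maximal runs.  Rows with zero total have
    undefined (NaN) probabilities.
    """

    counts: pd.DataFrame
    probabilities: pd.DataFrame

    @property
    def states(self) -> list:
        return list(self.counts.index)


def transition_matrix(subsegments: pd.DataFrame, states=None) -> TransitionMatrix:
    """Tally transitions between consecutive subsegments within segments.

    Every subsegment contributes exactly one transition: to the next
    subsegment of its segment, or to ``segment_end`` if it is the last.
    """
    if states is None:
        states = sorted(subsegments["behavior"].unique().tolist())
    cols = list(states) + [SEGMENT_END]
    counts = pd.DataFrame(0, index=list(states), columns=cols, dtype=int)
    if len(subsegments):
        beh = subsegments["behavior"].to_numpy()
        animal = subsegments["animal_id"].to_numpy()
        seg = subsegments["segment_id"].to_numpy()
        same_seg = np.zeros(len(subsegments), dtype=bool)
        same_seg[:-1] = (animal[1:] == animal[:-1]) & (seg[1:] == seg[:-1])
        nxt = np.empty(len(subsegments), dtype=object)
        nxt[:-1] = beh[1:]
        nxt[~same_seg] = SEGMENT_END
        tally = pd.crosstab(pd.Series(beh), pd.Series(nxt))
        counts = (
            counts.add(tally.reindex(index=counts.index, columns=cols, fill_value=0),
                       fill_value=0)
            .astype(int)
        )
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        probs = counts.div(totals.where(totals > 0), axis=0)
    return TransitionMatrix(counts=counts, probabilities=probs)


def duration_bins(
    subsegments: pd.DataFrame, edges=(0.0, 22.0)
) -> pd.DataFrame:
    """Per-behavior proportions of subsegment durations in standard bins.

    Default bins: exactly 0 s (single points); (0, 22] s; > 22 s.  ``edges``
    are the strictly increasing interior boundaries; each bin is half-open
    on the left, and durations equal to the first edge form their own bin.
    """
    edges = list(edges)
    if sorted(set(edges)) != edges:
        raise ValueError("bin edges must be strictly increasing and non-overlapping")
    labels = [f"{edges[0]:g}s"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{lo:g}-{hi:g}s")
    labels.append(f">{edges[-1]:g}s")

    def binify(d: float) -> str:
        if d <= edges[0]:
            return labels[0]
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if lo < d <= hi:
                return labels[i + 1]
        return labels[-1]

    df = subsegments.assign(_bin=subsegments["duration"].map(binify))
    counts = (
        df.groupby(["behavior", "_bin"], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=labels, fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    props["count"] = counts.sum(axis=1)
    props.columns.name = None
    props.index.name = "behavior"
    return props


def cluster_summaries(
    features: pd.DataFrame, labels, behavior_map: dict | None = None
) -> pd.DataFrame:
    """Five-number summaries plus 1.5×IQR whisker bounds per cluster.

    Computed per focal variable on the original (untransformed) scale with
    linear-interpolation quantiles.  Empty clusters yield rows of NaN.
    """
    labels = np.asarray(labels)
    rows = []
    for cl in np.unique(labels):
        sub = features.loc[labels == cl]
        name = behavior_map.get(cl, f"cluster_{cl}") if behavior_map else f"cluster_{cl}"
        for var in FOCAL_VARIABLES:
            if var not in features.columns:
                continue
            v = sub[var].dropna().to_numpy()
            if len(v) == 0:
                rows.append(
                    {"cluster": cl, "behavior": name, "variable": var,
                     **{s: np.nan for s in
                        ("min", "q1", "median", "q3", "max",
                         "whisker_lo", "whisker_hi")},
                     "n": 0}
                )
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            rows.append(
                {
                    "cluster": cl,
                    "behavior": name,
                    "variable": var,
                    "min": v.min(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": v.max(),
                    "whisker_lo": max(v.min(), q1 - 1.5 * iqr),
                    "whisker_hi": min(v.max(), q3 + 1.5 * iqr),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def crosstab_by_group(labeled: pd.DataFrame, by) -> pd.DataFrame:
    """Behavior proportions per group (life stage and/or age class).

    ``by`` is a column name or list of names present in ``labeled``; any
    value found there — known or not — forms its own level.  Returns the
    per-group behavior proportions with a marginal ``pct_points`` column
    (percent of all points in that group).
    """
    if labeled.empty:
        return pd.DataFrame()
    by = [by] if isinstance(by, str) else list(by)
    for col in by:
        if col not in labeled.columns:
            raise ValueError(f"grouping column '{col}' not present")
    counts = (
        labeled.groupby(by + ["behavior"], observed=True, dropna=False)
        .size()
        .unstack("behavior", fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props["pct_points"] = 100.0 * counts.sum(axis=1) / counts.values.sum()
    return props
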