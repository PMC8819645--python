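"""Model facade: fit a point-based flight-behavior classification to a fix table.

:class:`FlightStateModel` holds the data and run configuration, runs the
deterministic preparation pipeline (ground-elevation attachment, first-tier
quality filter, focal-variable computation, second-tier segment filter,
square-root transform and standardization) once, and exposes

* :meth:`FlightStateModel.fit` — multi-start K-means at one K, returning a
  :class:`FlightStateResults`;
* :meth:`FlightStateModel.select_k` — the elbow curve, bootstrapped
  silhouettes and PCA biplot data over a range of K.

The results object carries the fitted partition aligned back to the input
rows, behavior naming, and the downstream behavioral summaries
(subsegments, duration bins, transition matrix, per-cluster boxplot
statistics, group crosstabs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import features as _features
from . import filtering as _filtering
from . import segmentation as _segmentation
from . import selection as _selection
from .config import FOCAL_VARIABLES, RunConfig
from .io import attach_ground_elevation, read_fixes, write_classified


class FlightStateModel:
    """Point-based behavioral classification of short-interval GPS tracks.

    Parameters
    ----------
    fixes
        Canonical fix table (see :func:`flightmodes.io.read_fixes`),
        time-ordered within animal.
    config
        Run configuration; defaults follow the standard thresholds
        (HDOP/VDOP ≤ 10, AGL ≥ −50 m, 11 s gaps, ≥3-point segments).
    dem
        Optional ground elevation: scalar, ESRI ASCII grid or path.  Not
        needed when ``fixes`` already has a ``ground_elev`` column.
    """

    def __init__(self, fixes: pd.DataFrame, config: RunConfig | None = None, dem=None):
        self.config = config or RunConfig()
        if dem is not None:
            fixes = attach_ground_elevation(fixes, dem)
        self.fixes = fixes.reset_index(drop=True)
        self._prepared = False

    @classmethod
    def from_csv(
        cls,
        path,
        config: RunConfig | None = None,
        dem=None,
        column_map: dict | None = None,
    ) -> "FlightStateModel":
        return cls(read_fixes(path, column_map=column_map), config=config, dem=dem)

    # -- preparation -------------------------------------------------------

    def prepare(self) -> "FlightStateModel":
        """Run filters, features and the standardizing transform (idempotent)."""
        if self._prepared:
            return self
        cfg = self.config
        tier1, self.first_tier_report = _filtering.first_tier_filter(self.fixes, cfg)
        feats = _features.compute_focal_variables(tier1, max_gap=cfg.max_gap)
        table = pd.concat([tier1[["animal_id", "t"]], feats], axis=1)
        retained, self.second_tier_report = _filtering.second_tier_filter(table, cfg)
        self.features_all = feats  # original scale, first-tier index
        self.retained = retained  # focal vars + animal_id, t, segment_id
        if len(retained):
            self.X, self.scaling = _features.fit_transform(
                retained[list(FOCAL_VARIABLES)]
            )
        else:
            raise ValueError("no fixes survive filtering; nothing to fit")
        self._prepared = True
        return self

    # -- fitting -----------------------------------------------------------

    def fit(
        self, k: int = 4, behavior_map: dict[int, str] | None = None
    ) -> "FlightStateResults":
        """Multi-start K-means at ``k`` on the standardized focal variables."""
        self.prepare()
        cfg = self.config
        km = _cluster.kmeans_fit(
            self.X.to_numpy(),
            k,
            n_starts=cfg.n_starts,
            max_iter=cfg.max_iter,
            seed=cfg.seed,
            scaling=self.scaling,
        )
        return FlightStateResults(self, km, behavior_map=behavior_map)

    def select_k(
        self,
        k_range=None,
        b: int | None = None,
        n_boot: int | None = None,
        max_biplot_points: int = 5000,
    ) -> "KSelectionReport":
        """Elbow curve, bootstrapped silhouettes and biplot data over K."""
        self.prepare()
        cfg = self.config
        k_range = tuple(k_range or cfg.k_range)
        b = b or cfg.n_boot_replicates
        n_boot = n_boot or cfg.boot_sample_size
        X = self.X.to_numpy()
        models = _cluster.fit_k_range(
            X, k_range, n_starts=cfg.n_starts, max_iter=cfg.max_iter,
            seed=cfg.seed, scaling=self.scaling,
        )
        wss = pd.DataFrame(
            {"k": list(models), "wss": [m.wss for m in models.values()]}
        )
        labels_per_k = {k: m.labels for k, m in models.items()}
        boots = _selection.bootstrap_silhouette(
            X, labels_per_k, b=b, n_boot=n_boot, seed=cfg.seed + 1
        )
        report = _selection.select_k(wss, boots)
        pca = _selection.pca_biplot_data(
            X, labels_per_k, max_points=max_biplot_points, seed=cfg.seed + 2
        )
        return KSelectionReport(
            report=report, wss=wss, bootstraps=boots, pca=pca, models=models
        )


@dataclass
class KSelectionReport:
    """Advisory K-selection diagnostics (no automatic decision)."""

    report: pd.DataFrame
    wss: pd.DataFrame
    bootstraps: dict
    pca: _selection.PcaSummary
    models: dict

    def __str__(self) -> str:
        lines = [
            "K-selection diagnostics (advisory; combine with biplots and",
            "the scientific question before fixing K)",
            "",
            self.report.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "PC1+PC2 variance: "
            f"{self.pca.pct_variance[:2].sum():.1f}%",
        ]
        return "\n".join(lines)


class FlightStateResults:
    """A fitted behavioral classification.

    Attributes
    ----------
    kmeans : KMeansResult
        The winning multi-start K-means partition.
    labels : pandas.Series
        Cluster id (1..K) per *input* fix; NaN for fixes removed by either
        filter tier (nullable integer dtype).
    behavior_map : dict
        Cluster id → behavior name (automatic unless overridden).
    """

    def __init__(
        self,
        model: FlightStateModel,
        kmeans: _cluster.KMeansResult,
        behavior_map: dict[int, str] | None = None,
    ):
        self.model = model
        self.kmeans = kmeans
        if behavior_map is None:
            try:
                behavior_map = _segmentation.label_behaviors(kmeans)
            except _segmentation.LabelingError:
                behavior_map = {
                    i + 1: f"cluster_{i + 1}" for i in range(kmeans.k)
                }
        self.behavior_map = behavior_map

        idx = model.retained.index
        lab = pd.Series(pd.NA, index=model.fixes.index, dtype="Int64")
        lab.loc[idx] = kmeans.labels
        self.labels = lab
        seg = pd.Series(pd.NA, index=model.fixes.index, dtype="Int64")
        seg.loc[idx] = model.retained["segment_id"].to_numpy()
        self.segment_ids = seg

    # -- basic accessors ---------------------------------------------------

    @property
    def k(self) -> int:
        return self.kmeans.k

    @property
    def wss(self) -> float:
        return self.kmeans.wss

    def centroids_natural(self) -> pd.DataFrame:
        """Centroids de-standardized to natural units, named by behavior."""
        cents = self.model.scaling.destandardize(self.kmeans.centroids)
        cents.index = [self.behavior_map[i + 1] for i in range(self.k)]
        return cents

    def classified_frame(self) -> pd.DataFrame:
        """Input fixes with features, cluster, behavior and segment columns."""
        m = self.model
        out = m.fixes.copy()
        for col in FOCAL_VARIABLES:
            out[col] = m.features_all[col]
        out["cluster"] = self.labels
        out["behavior"] = self.labels.map(
            {k: v for k, v in self.behavior_map.items()}
        )
        out["segment_id"] = self.segment_ids
        sub = self.subsegments()
        out["subsegment_id"] = self._per_fix_subsegment_ids(sub)
        return out

    def _labeled_retained(self) -> pd.DataFrame:
        m = self.model
        df = m.retained[["animal_id", "t", "segment_id"]].copy()
        df["cluster"] = self.kmeans.labels
        df["behavior"] = [self.behavior_map[l] for l in self.kmeans.labels]
        return df

    def _per_fix_subsegment_ids(self, sub: pd.DataFrame) -> pd.Series:
        m = self.model
        out = pd.Series(pd.NA, index=m.fixes.index, dtype="Int64")
        if sub.empty:
            return out
        reps = np.repeat(sub["subsegment_id"].to_numpy(), sub["n_points"].to_numpy())
        out.loc[m.retained.index] = reps
        return out

    # -- behavioral summaries ---------------------------------------------

    def subsegments(self) -> pd.DataFrame:
        """Maximal same-behavior runs within segments."""
        return _segmentation.find_subsegments(self._labeled_retained())

    def transition_matrix(self, states=None) -> _segmentation.TransitionMatrix:
        order = states or [
            self.behavior_map[i + 1] for i in range(self.k)
        ]
        return _segmentation.transition_matrix(self.subsegments(), states=order)

    def duration_bins(self, edges=(0.0, 22.0)) -> pd.DataFrame:
        return _segmentation.duration_bins(self.subsegments(), edges=edges)

    def cluster_summaries(self) -> pd.DataFrame:
        m = self.model
        return _segmentation.cluster_summaries(
            m.retained[list(FOCAL_VARIABLES)],
            self.kmeans.labels,
            behavior_map=self.behavior_map,
        )

    def crosstab_by_group(self, by) -> pd.DataFrame:
        m = self.model
        cols = [by] if isinstance(by, str) else list(by)
        missing = [c for c in cols if c not in m.fixes.columns]
        if missing:
            raise ValueError(f"grouping column(s) not in fixes: {missing}")
        df = m.fixes.loc[m.retained.index, cols].copy()
        df["behavior"] = [self.behavior_map[l] for l in self.kmeans.labels]
        return _segmentation.crosstab_by_group(df, by=cols)

    # -- prediction and export --------------------------------------------

    def predict(self, new_fixes: pd.DataFrame, dem=None) -> pd.Series:
        """Classify new fixes with the saved transform and centroids.

        The new data go through the same preparation (filters, features,
        stored scaling); fixes that do not survive get NA.
        """
        sub = FlightStateModel(new_fixes, config=self.model.config, dem=dem)
        cfg = sub.config
        tier1, _ = _filtering.first_tier_filter(sub.fixes, cfg)
        feats = _features.compute_focal_variables(tier1, max_gap=cfg.max_gap)
        table = pd.concat([tier1[["animal_id", "t"]], feats], axis=1)
        retained, _ = _filtering.second_tier_filter(table, cfg)
        out = pd.Series(pd.NA, index=sub.fixes.index, dtype="Int64")
        if len(retained):
            Xn = _features.apply_transform(
                retained[list(FOCAL_VARIABLES)], self.model.scaling
            )
            out.loc[retained.index] = _cluster.assign(Xn.to_numpy(), self.kmeans)
        return out

    def save(self, path) -> None:
        """Serialize centroids, K, seed and scaling to a JSON text file."""
        self.kmeans.to_json(path)

    def to_csv(self, path) -> None:
        """Write the classified fix table (one row per input fix)."""
        frame = self.classified_frame()
        write_classified(
            path,
            self.model.fixes,
            features=frame[list(FOCAL_VARIABLES)],
            labels=frame["cluster"],
            behaviors=frame["behavior"],
            segment_ids=frame["segment_id"],
            subsegment_ids=frame["subsegment_id"],
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary: filters, fit, centroids, behaviors."""
        m = self.model
        cents = self.centroids_natural()
        lines = [
            "Flight-behavior classification (point-based K-means)",
            "=" * 56,
            f"K = {self.k}   starts = {self.kmeans.n_starts}   "
            f"WSS = {self.wss:.2f}   seed = {self.kmeans.seed}",
            "",
            "First-tier filter",
            "-" * 17,
            str(self.model.first_tier_report),
            "",
            "Second-tier filter",
            "-" * 18,
            str(self.model.second_tier_report),
            "",
            "Centroids (natural units)",
            "-" * 25,
            cents.to_string(float_format=lambda v: f"{v:9.2f}"),
            "",
            "Points per behavior",
            "-" * 19,
        ]
        counts = pd.Series(self.kmeans.labels).map(self.behavior_map).value_counts()
        for name, cnt in counts.items():
            lines.append(f"  {name:<12} {cnt:>8}  ({100 * cnt / len(m.retained):.1f}%)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<FlightStateResults K={self.k} wss={self.wss:.2f} "
            f"n={int(self.labels.notna().sum())}/{len(self.labels)} fixes>"
        )
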