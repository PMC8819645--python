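"""Choosing the number of clusters K.

Three complementary diagnostics, none of which auto-decides:

* the elbow (WSS-vs-K) curve from :func:`flightmodes.cluster.wss_curve`;
* bootstrapped average silhouette widths — with millions of fixes the full
  n×n distance matrix is infeasible, so the average silhouette is computed
  on ``B`` resamples of ``n_boot`` points drawn with replacement, holding
  the full-data cluster labels fixed;
* PCA biplot data (loadings, percent variance, seeded score subsample
  colored per candidate K) for the visual "lineup".

The final choice of K remains with the analyst: high silhouettes can favor
a coarse split (e.g. stationary vs in-flight) that hides biologically
distinct flight modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import FOCAL_VARIABLES

logger = logging.getLogger(__name__)


def silhouette_values(X, labels) -> np.ndarray:
    """Exact silhouette width of every point.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)) where a(i) is the mean Euclidean
    distance to the other members of i's cluster and b(i) the smallest mean
    distance to the members of any other cluster.  Points in singleton
    clusters get 0 by convention.  Requires at least two distinct clusters.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq, idx = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("silhouette requires at least two clusters")
    n = X.shape[0]
    D = cdist(X, X)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), idx] = 1.0
    sums = D @ onehot  # (n, k) total distance to each cluster
    counts = onehot.sum(axis=0)

    own = sums[np.arange(n), idx]
    own_count = counts[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = own / (own_count - 1)
    mean_other = sums / counts
    mean_other[np.arange(n), idx] = np.inf
    b = mean_other.min(axis=1)
    with np.errstate(invalid="ignore"):
        s = (b - a) / np.maximum(a, b)
    s = np.where(own_count == 1, 0.0, s)
    s = np.where(np.maximum(a, b) == 0, 0.0, s)  # coincident clusters
    return s


def silhouette_width(i: int, X, labels) -> float:
    """Silhouette width of point ``i`` (convenience scalar form)."""
    return float(silhouette_values(X, labels)[i])


@dataclass
class SilhouetteBootstrap:
    """B bootstrapped average silhouette widths for one K."""

    k: int
    b: int
    n_boot: int
    values: np.ndarray  # (b,), NaN where a replicate was invalid
    seed: int
    n_invalid: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def percentile(self, q) -> float:
        return float(np.nanpercentile(self.values, q))


def bootstrap_silhouette(
    X,
    labels_per_k: dict[int, np.ndarray],
    b: int = 1000,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict[int, SilhouetteBootstrap]:
    """Bootstrap the average silhouette for each candidate K.

    Each replicate draws ``n_boot`` row indices with replacement — the same
    indices for every K, so candidates are compared on identical resamples —
    and averages the silhouette widths of the resampled points under their
    fixed full-data labels.  Duplicated rows are retained as distinct points
    at distance zero.  A replicate whose resample contains fewer than two
    distinct clusters for some K is recorded as NaN for that K and counted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    labels_per_k = {k: np.asarray(v) for k, v in labels_per_k.items()}
    for k, lab in labels_per_k.items():
        if len(lab) != n:
            raise ValueError(f"labels for K={k} have length {len(lab)} != n={n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = {k: np.full(b, np.nan) for k in labels_per_k}
    invalid = {k: 0 for k in labels_per_k}
    for rep in range(b):
        idx = rng.integers(0, n, size=n_boot)
        Xs = X[idx]
        for k, lab in labels_per_k.items():
            sub = lab[idx]
            if len(np.unique(sub)) < 2:
                invalid[k] += 1
                logger.warning(
                    "bootstrap replicate %d has <2 clusters for K=%d", rep, k
                )
                continue
            values[k][rep] = float(np.mean(silhouette_values(Xs, sub)))
    return {
        k: SilhouetteBootstrap(
            k=k, b=b, n_boot=n_boot, values=values[k], seed=seed,
            n_invalid=invalid[k],
        )
        for k in labels_per_k
    }


def select_k(
    wss: pd.DataFrame, boots: dict[int, SilhouetteBootstrap]
) -> pd.DataFrame:
    """Advisory per-K report: WSS, silhouette mean and 95% interval, rank.

    Ranks candidates by mean bootstrapped silhouette (ties broken by the
    smaller K).  The ranking is advisory only — a final choice should also
    weigh the biplot lineup and the scientific question.
    """
    if len(boots) < 2:
        raise ValueError("select_k needs at least two candidate K")
    rows = []
    for k, bs in sorted(boots.items()):
        rows.append(
            {
                "k": k,
                "sil_mean": bs.mean,
                "sil_q2_5": bs.percentile(2.5),
                "sil_q97_5": bs.percentile(97.5),
                "n_invalid": bs.n_invalid,
            }
        )
    report = pd.DataFrame(rows).merge(wss, on="k", how="left")
    order = report.sort_values(
        ["sil_mean", "k"], ascending=[False, True], kind="stable"
    )["k"].tolist()
    report["rank"] = report["k"].map({k: i + 1 for i, k in enumerate(order)})
    report = report.sort_values("rank").reset_index(drop=True)
    report.attrs["note"] = (
        "advisory ranking by mean bootstrapped silhouette; combine with the "
        "elbow curve and PCA biplot lineup before fixing K"
    )
    return report


@dataclass
class PcaSummary:
    """Loadings, percent variance and plot-ready scores of a PCA."""

    loadings: pd.DataFrame  # (p, p) columns PC1..PCp, orthonormal
    pct_variance: np.ndarray  # (p,), sums to 100
    scores: pd.DataFrame  # subsample scores, columns PC1..PCp
    sample_index: np.ndarray  # row positions of the plotted subsample
    labels_per_k: dict  # K -> labels of the plotted subsample


def pca_biplot_data(
    X,
    labels_per_k: dict[int, np.ndarray] | None = None,
    max_points: int = 5000,
    seed: int = 0,
    columns=FOCAL_VARIABLES,
) -> PcaSummary:
    """Eigen-decomposition of the covariance of the standardized matrix.

    Because the inputs are already standardized this is a correlation-scale
    PCA of the raw features.  Scores are returned for a seeded subsample of
    ``max_points`` rows, once per candidate K colored by that K's labels.
    Eigenvector signs are normalized (largest-magnitude loading positive)
    so outputs are deterministic; zero eigenvalues are permitted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    pct = 100.0 * eigval / eigval.sum()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n > max_points:
        sample = np.sort(rng.choice(n, size=max_points, replace=False))
    else:
        sample = np.arange(n)
    pc_cols = [f"PC{i+1}" for i in range(p)]
    scores = pd.DataFrame(X[sample] @ eigvec, columns=pc_cols)
    cols = list(columns)[:p] if len(columns) >= p else [f"v{i}" for i in range(p)]
    loadings = pd.DataFrame(eigvec, index=cols, columns=pc_cols)
    sub_labels = {
        k: np.asarray(lab)[sample] for k, lab in (labels_per_k or {}).items()
    }
    return PcaSummary(
        loadings=loadings,
        pct_variance=pct,
        scores=scores,
        sample_index=sample,
        labels_per_k=sub_labels,
    )
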