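"""Multi-start K-means in standardized feature space.

Lloyd's algorithm with the classical random-partition initialization: each
start assigns every point a uniform-random label in 1..K, then alternates
centroid updates and nearest-centroid reassignment until the labels stop
changing.  The best of ``n_starts`` runs (minimum total within-cluster sum
of squared Euclidean distances, WSS) is returned.  Should a cluster empty
out during iteration — possible under random-label initialization — its
centroid is re-seeded at the point currently farthest from its own
centroid, keeping K fixed.

All randomness descends from one seed through per-start
:class:`numpy.random.SeedSequence` substreams, so fits are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import ScalingParams


@dataclass
class KMeansResult:
    """A fitted K-means partition in standardized feature space."""

    k: int
    centroids: np.ndarray  # (k, p)
    labels: np.ndarray  # (n,), values in 1..k
    wss: float
    n_starts: int
    seed: int
    n_iter_per_start: list = field(default_factory=list)
    converged_per_start: list = field(default_factory=list)
    scaling: ScalingParams | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "wss": self.wss,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KMeansResult":
        with open(path) as fh:
            d = json.load(fh)
        scaling = ScalingParams.from_dict(d["scaling"]) if d.get("scaling") else None
        return cls(
            k=d["k"],
            centroids=np.asarray(d["centroids"], dtype=float),
            labels=np.empty(0, dtype=int),
            wss=d["wss"],
            n_starts=d["n_starts"],
            seed=d["seed"],
            scaling=scaling,
        )


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    return X


def _update_centroids(X: np.ndarray, labels0: np.ndarray, k: int) -> np.ndarray:
    """Mean of each cluster; empty clusters re-seeded at the worst-fit point."""
    n, p = X.shape
    counts = np.bincount(labels0, minlength=k)
    sums = np.zeros((k, p))
    np.add.at(sums, labels0, X)
    centroids = np.where(counts[:, None] > 0, sums / np.maximum(counts, 1)[:, None], 0.0)
    empty = np.flatnonzero(counts == 0)
    if len(empty):
        d_own = np.einsum(
            "ij,ij->i", X - centroids[labels0], X - centroids[labels0]
        )
        order = np.argsort(-d_own)
        used = 0
        for ke in empty:
            centroids[ke] = X[order[used]]
            used += 1
    return centroids


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = X.shape[0]
    labels0 = rng.integers(0, k, size=n)
    converged = False
    wss_prev = np.inf
    for it in range(1, max_iter + 1):
        centroids = _update_centroids(X, labels0, k)
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)  # argmin ties -> lowest index
        wss = float(d2[np.arange(n), new_labels].sum())
        # Lloyd monotonicity: the objective never increases across iterations
        assert wss <= wss_prev * (1 + 1e-12) + 1e-12, "WSS increased in Lloyd step"
        wss_prev = wss
        if np.array_equal(new_labels, labels0):
            converged = True
            labels0 = new_labels
            break
        labels0 = new_labels
    centroids = _update_centroids(X, labels0, k)
    d2 = cdist(X, centroids, metric="sqeuclidean")
    wss = float(d2[np.arange(n), labels0].sum())
    return labels0, centroids, wss, it, converged


def kmeans_fit(
    X,
    k: int,
    n_starts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    scaling: ScalingParams | None = None,
) -> KMeansResult:
    """Fit K-means with ``n_starts`` random-partition restarts.

    Returns the start achieving the smallest WSS.  Labels are reported in
    1..K.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= n, got K={k}, n={n}")
    streams = np.random.SeedSequence(seed).spawn(n_starts)
    best = None
    iters, convs = [], []
    for ss in streams:
        rng = np.random.default_rng(ss)
        labels0, centroids, wss, n_iter, converged = _lloyd(X, k, rng, max_iter)
        iters.append(n_iter)
        convs.append(converged)
        if best is None or wss < best[2]:
            best = (labels0, centroids, wss)
    labels0, centroids, wss = best
    return KMeansResult(
        k=k,
        centroids=centroids,
        labels=labels0 + 1,
        wss=wss,
        n_starts=n_starts,
        seed=seed,
        n_iter_per_start=iters,
        converged_per_start=convs,
        scaling=scaling,
    )


def assign(X, model: KMeansResult) -> np.ndarray:
    """Nearest-centroid labels (1..K) for new standardized rows.

    Ties go to the lowest cluster index.
    """
    X = _as_matrix(X)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.centroids.shape[1]}"
        )
    d2 = cdist(X, model.centroids, metric="sqeuclidean")
    return np.argmin(d2, axis=1) + 1


def fit_k_range(
    X,
    k_range,
    n_starts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    scaling: ScalingParams | None = None,
) -> dict[int, KMeansResult]:
    """One multi-start fit per candidate K, deterministic given ``seed``."""
    streams = np.random.SeedSequence(seed).spawn(len(list(k_range)))
    out = {}
    for k, ss in zip(k_range, streams):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        out[k] = kmeans_fit(
            X, k, n_starts=n_starts, max_iter=max_iter, seed=sub_seed, scaling=scaling
        )
    return out


def wss_curve(
    X, k_range, n_starts: int = 10, max_iter: int = 100, seed: int = 0
) -> pd.DataFrame:
    """WSS as a function of K for the elbow plot."""
    models = fit_k_range(X, k_range, n_starts=n_starts, max_iter=max_iter, seed=seed)
    return pd.DataFrame(
        {"k": list(models), "wss": [m.wss for m in models.values()]}
    )
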