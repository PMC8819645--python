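"""Diagnostic plots: elbow curve, silhouette bands, biplot lineup, boxplots."""

from __future__ import annotations

import numpy as np

from .selection import PcaSummary


def plot_elbow(wss, ax=None):
    """WSS as a function of K."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(wss["k"], wss["wss"], "o-")
    ax.set_xlabel("number of clusters K")
    ax.set_ylabel("total within-cluster sum of squares")
    return ax


def plot_silhouette(bootstraps: dict, ax=None):
    """Bootstrapped average silhouette per K: replicates, mean, 95% band."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ks = sorted(bootstraps)
    means = [bootstraps[k].mean for k in ks]
    lo = [bootstraps[k].percentile(2.5) for k in ks]
    hi = [bootstraps[k].percentile(97.5) for k in ks]
    for k in ks:
        vals = bootstraps[k].values
        jitter = np.linspace(-0.12, 0.12, len(vals))
        ax.plot(k + jitter, vals, ".", color="0.7", ms=2, zorder=1)
    ax.fill_between(ks, lo, hi, alpha=0.25, zorder=2)
    ax.plot(ks, means, "o-", color="goldenrod", zorder=3)
    ax.set_xlabel("number of clusters K")
    ax.set_ylabel("bootstrapped average silhouette width")
    return ax


def plot_biplot(pca: PcaSummary, k: int | None = None, ax=None, arrow_scale=3.0):
    """Scores on PC1/PC2 (colored by a candidate K's labels) with loadings."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    scores = pca.scores
    colors = None
    if k is not None and k in pca.labels_per_k:
        colors = pca.labels_per_k[k]
    ax.scatter(scores["PC1"], scores["PC2"], c=colors, s=4, cmap="viridis", alpha=0.6)
    for var, row in pca.loadings.iterrows():
        ax.annotate(
            var,
            xy=(0, 0),
            xytext=(arrow_scale * row["PC1"], arrow_scale * row["PC2"]),
            arrowprops=dict(arrowstyle="<-", color="crimson"),
            color="crimson",
        )
    ax.set_xlabel(f"PC1 ({pca.pct_variance[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({pca.pct_variance[1]:.0f}%)")
    if k is not None:
        ax.set_title(f"K = {k}")
    return ax


def plot_cluster_boxes(summaries, variable: str, ax=None):
    """Boxplot-style rendering of per-cluster five-number summaries."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sub = summaries[summaries["variable"] == variable]
    stats = [
        {
            "label": row["behavior"],
            "whislo": row["whisker_lo"],
            "q1": row["q1"],
            "med": row["median"],
            "q3": row["q3"],
            "whishi": row["whisker_hi"],
            "fliers": [],
        }
        for _, row in sub.iterrows()
    ]
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel(variable)
    return ax
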