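"""Basic figures: score plots, S-plots, clustered heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def score_plot(scores, groups=None, ax=None, comps=(0, 1)):
    """Scatter of latent-variable scores, colored by group."""
    if ax is None:
        _, ax = plt.subplots()
    scores = np.asarray(scores)
    if groups is None:
        ax.scatter(scores[:, comps[0]], scores[:, comps[1]], s=20)
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            m = groups == g
            ax.scatter(scores[m, comps[0]], scores[m, comps[1]], s=20, label=str(g))
        ax.legend()
    ax.set_xlabel(f"component {comps[0] + 1}")
    ax.set_ylabel(f"component {comps[1] + 1}")
    return ax


def s_plot_figure(opls_model, ax=None, annotate_top: int = 5):
    """Covariance vs correlation S-plot of an OPLS-DA model."""
    from .multivariate import s_plot

    if ax is None:
        _, ax = plt.subplots()
    coords = s_plot(opls_model)
    ax.scatter(coords["p1"], coords["p_corr"], s=15)
    extremes = coords.reindex(coords["p1"].abs().sort_values(ascending=False).index)
    for name, row in extremes.head(annotate_top).iterrows():
        ax.annotate(str(name), (row["p1"], row["p_corr"]), fontsize=7)
    ax.set_xlabel("p[1] (covariance)")
    ax.set_ylabel("p(corr)[1] (correlation)")
    return ax


def clustered_heatmap(X, hca_result, sample_ids=None, feature_names=None, ax=None):
    """Heatmap with rows (and columns, if biclustered) in dendrogram order."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    M = np.asarray(X, dtype=float)
    rows = hca_result.row_order
    cols = (
        hca_result.col_order if hca_result.col_order is not None else np.arange(M.shape[1])
    )
    im = ax.imshow(M[np.ix_(rows, cols)], aspect="auto", cmap="RdBu_r")
    if sample_ids is not None:
        ax.set_yticks(range(len(rows)))
        ax.set_yticklabels([sample_ids[i] for i in rows], fontsize=6)
    if feature_names is not None:
        ax.set_xticks(range(len(cols)))
        ax.set_xticklabels([feature_names[i] for i in cols], rotation=90, fontsize=6)
    plt.colorbar(im, ax=ax, shrink=0.7)
    return ax
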