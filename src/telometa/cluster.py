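"""Correlation-profile clustering and the significant-metabolite correlogram.

Metabolites are clustered by their two-entry correlation-with-LTL profile
(model 1 r, model 2 r) with agglomerative hierarchical clustering, euclidean
distance and complete linkage.  Rows are sorted lexicographically by
metabolite name before linkage so tie-breaking is deterministic and
independent of input order.  The correlogram is the pairwise-complete Pearson
correlation matrix of the ln-concentrations of a metabolite subset within one
cohort.

Figures are rendered as images, but every number plotted is also written to a
TSV companion (heat-map ordering and correlogram long format); tests and
downstream consumers rely on the TSVs, never on pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "HclustResult",
    "hclust_order",
    "correlogram",
    "render_heatmap",
    "render_correlogram",
]


@dataclass
class HclustResult:
    labels: list[str]          # lexicographic input order used for linkage
    linkage: np.ndarray        # scipy linkage matrix (complete, euclidean)
    leaf_order: list[str]      # dendrogram leaf order
    clusters: pd.Series        # two-cluster cut, metabolite -> {1, 2}


def hclust_order(profiles: pd.DataFrame, n_clusters: int = 2) -> HclustResult:
    """Cluster metabolite correlation profiles (rows) hierarchically.

    ``profiles`` is indexed by metabolite with numeric profile columns
    (typically r_model1, r_model2).  Returns the linkage matrix, merge
    heights, deterministic leaf order and an ``n_clusters``-cut labelling.
    """
    if len(profiles) < 2:
        raise ValueError("hclust_order requires at least 2 profiles")
    prof = profiles.sort_index(kind="mergesort")
    X = prof.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    labels = list(prof.index)
    cut = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return HclustResult(
        labels=labels,
        linkage=Z,
        leaf_order=[labels[i] for i in leaves],
        clusters=pd.Series(cut, index=labels, name="cluster"),
    )


def correlogram(ln_matrix: pd.DataFrame, labels: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and p-values) of selected metabolites.

    Pairwise-complete observations; two-sided p from the t reference with
    n-2 degrees of freedom.  Returns symmetric (r, p) DataFrames.
    """
    missing = [m for m in labels if m not in ln_matrix.columns]
    if missing:
        raise ValueError(f"metabolites not in matrix: {missing}")
    if len(labels) < 2:
        raise ValueError("correlogram requires at least 2 metabolites")
    sub = ln_matrix[labels]
    for m in labels:
        v = sub[m].dropna()
        if v.nunique() < 2:
            raise ValueError(f"zero-variance column {m!r}")
    k = len(labels)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub[[labels[i], labels[j]]].dropna()
            if len(pair) < 4:
                raise ValueError(f"too few complete pairs for {labels[i]!r} vs {labels[j]!r}")
            rij, pij = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=labels, columns=labels)
    pdf = pd.DataFrame(p, index=labels, columns=labels)
    return rdf, pdf


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def render_heatmap(
    profiles: pd.DataFrame,
    stars: pd.DataFrame,
    result: HclustResult,
    png_path,
    tsv_path,
) -> None:
    """Heat map of LTL-correlation profiles in dendrogram leaf order.

    Writes the image and a TSV companion with the exact plotted numbers
    (metabolite, cluster, one r and one stars column per model); the TSV is
    byte-deterministic for identical input.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = result.leaf_order
    prof = profiles.loc[order]
    rows = []
    for met in order:
        row = {"metabolite": met, "cluster": int(result.clusters[met])}
        for col in profiles.columns:
            row[col] = _fmt(float(prof.loc[met, col]))
        for col in stars.columns:
            row[f"stars_{col}"] = stars.loc[met, col]
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(4, max(3, 0.18 * len(order))))
    vmax = max(1e-9, float(np.abs(prof.to_numpy()).max()))
    im = ax.imshow(prof.to_numpy(dtype=float), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(prof.columns)), labels=list(prof.columns))
    ax.set_yticks(range(len(order)), labels=order, fontsize=5)
    fig.colorbar(im, ax=ax, label="partial correlation with LTL")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)


def render_correlogram(rdf: pd.DataFrame, pdf_: pd.DataFrame, png_path, tsv_path) -> None:
    """Circle-matrix correlogram plus a long-format TSV (met_a, met_b, r, p)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labels = list(rdf.columns)
    rows = []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            rows.append({"met_a": a, "met_b": b, "r": _fmt(rdf.iloc[i, j]), "p": _fmt(pdf_.iloc[i, j])})
    pd.DataFrame(rows, columns=["met_a", "met_b", "r", "p"]).to_csv(tsv_path, sep="\t", index=False)

    k = len(labels)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * k, 1 + 0.6 * k))
    cmap = plt.get_cmap("RdBu_r")
    for i in range(k):
        for j in range(k):
            r = rdf.iloc[i, j]
            ax.scatter(j, k - 1 - i, s=600 * abs(r), c=[cmap((r + 1) / 2)],
                       edgecolors="grey", linewidths=0.3)
    ax.set_xticks(range(k), labels=labels, rotation=90, fontsize=7)
    ax.set_yticks(range(k), labels=labels[::-1], fontsize=7)
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
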