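"""Embedding-space diagnostics: 2-D PCA projection and class separation.

A trained encoder should place same-class molecules close together and
different-class molecules apart. These helpers project embeddings onto the
top two principal components and score how well the true labels separate in
that plane with the silhouette coefficient — a quantitative stand-in for
the usual visual scatter-plot argument (near +1: tight, well-separated
class clusters; near 0: no structure; negative: classes inverted relative
to cluster assignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score


@dataclass
class ProjectionResult:
    coordinates: np.ndarray             # (n, 2)
    explained_variance_ratio: np.ndarray  # (2,), non-increasing
    components: np.ndarray              # (2, d) orthonormal rows
    labels: np.ndarray


def pca_project(embeddings: np.ndarray, labels: np.ndarray) -> ProjectionResult:
    """Project onto the top-2 principal components.

    Mean-centred eigen-decomposition of the covariance; deterministic up to
    sign, fixed by making each component's largest-magnitude loading
    positive. Raises on zero-variance input.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need an (n >= 3, d >= 2) embedding matrix")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    total_var = np.trace(cov)
    if total_var <= 1e-12:
        raise ValueError("zero-variance embeddings cannot be projected")
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigvals)[::-1][:2]
    comps = eigvecs[:, order].T  # (2, d)
    for i in range(2):
        if comps[i, np.argmax(np.abs(comps[i]))] < 0:
            comps[i] = -comps[i]
    coords = Xc @ comps.T
    ratio = np.clip(eigvals[order], 0.0, None) / total_var
    return ProjectionResult(coordinates=coords,
                            explained_variance_ratio=ratio,
                            components=comps,
                            labels=labels)


def separation_score(result: ProjectionResult) -> float:
    """Silhouette of the 2-D coordinates under the true labels, in [-1, 1]."""
    labels = np.asarray(result.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("separation score needs both classes present")
    return float(silhouette_score(result.coordinates, labels))


def plot_projection(result: ProjectionResult, path, title: str = "") -> None:
    """Scatter the projection coloured by class; writes an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in ((0, "tab:blue"), (1, "tab:red")):
        mask = result.labels == cls
        ax.scatter(result.coordinates[mask, 0], result.coordinates[mask, 1],
                   s=12, alpha=0.7, c=color, label=f"class {cls}")
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%} var)")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%} var)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
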