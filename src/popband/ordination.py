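"""Sokal-Michener dissimilarity and classical principal coordinates analysis.

The Sokal-Michener (simple matching) dissimilarity between two 0/1 band
profiles is the proportion of mismatching loci; both 1-1 and 0-0 count as
matches.  It equals AMOVA's squared distance divided by the locus count, so
the ordination and the variance partition view the same metric space.

PCoA follows the classical Torgerson construction: square the
dissimilarities, double-center B = -1/2 * J D^2 J, eigendecompose, and scale
eigenvectors by the square root of their eigenvalues.  Negative eigenvalues
are reported but excluded from the explained-variance percentages; no
Lingoes/Cailliez correction is applied.  Axis signs are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .io import BandMatrix

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "sokal_michener",
    "sokal_michener_matrix",
    "pcoa",
    "centroids",
    "plot_pcoa",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix with sample labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != d.shape[0]:
            raise ValueError("label count != matrix size")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class PcoaResult:
    """Coordinates, eigenvalues and explained-variance shares of a PCoA."""

    labels: tuple[str, ...]
    coordinates: np.ndarray      # samples x retained axes
    eigenvalues: np.ndarray      # all eigenvalues, decreasing (may be < 0)
    pct_variance: np.ndarray     # per retained axis, % of positive-eigenvalue sum


def sokal_michener(x, y) -> float:
    """Proportion of mismatching loci between two 0/1 vectors (0-0 matches)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.mean(x != y))


def sokal_michener_matrix(m: BandMatrix) -> DistanceMatrix:
    """All-pairs Sokal-Michener dissimilarities for a band matrix."""
    d = squareform(pdist(m.values.astype(float), metric="hamming"))
    return DistanceMatrix(m.sample_ids, d)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical (Torgerson) principal coordinates of a dissimilarity matrix.

    Retains the ``n_axes`` leading positive-eigenvalue axes (all of them by
    default).  ``pct_variance`` is computed over positive eigenvalues only and
    sums to <= 100.
    """
    n = d.d.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    d2 = d.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues: degenerate distance matrix")
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    pct = 100.0 * evals[:keep] / evals[pos].sum()
    return PcoaResult(d.labels, coords, evals, pct)


def centroids(r: PcoaResult, partition) -> dict[str, np.ndarray]:
    """Per-population arithmetic mean of member coordinates.

    ``partition`` maps each sample (by position) to a population label and
    must cover every sample.
    """
    labels = list(partition)
    if len(labels) != len(r.labels):
        raise ValueError("partition length != number of samples")
    out: dict[str, np.ndarray] = {}
    arr = np.asarray(labels)
    for pop in dict.fromkeys(labels):
        mask = arr == pop
        if not mask.any():
            raise ValueError(f"empty population {pop!r}")
        out[pop] = r.coordinates[mask].mean(axis=0)
    return out


def plot_pcoa(r: PcoaResult, partition, path, title: str = "PCoA") -> None:
    """Convenience scatter of the first two axes with population centroids."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cents = centroids(r, partition)
    arr = np.asarray(list(partition))
    fig, ax = plt.subplots(figsize=(6, 5))
    for pop in dict.fromkeys(partition):
        mask = arr == pop
        ax.scatter(r.coordinates[mask, 0], r.coordinates[mask, 1],
                   s=18, alpha=0.7, label=pop)
        ax.scatter(*cents[pop][:2], marker="x", s=140, lw=3, color="black")
    ax.set_xlabel(f"Axis 1 ({r.pct_variance[0]:.1f}%)")
    ax.set_ylabel(f"Axis 2 ({r.pct_variance[1]:.1f}%)"
                  if len(r.pct_variance) > 1 else "Axis 2")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
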