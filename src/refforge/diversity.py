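"""Alpha/beta diversity and ordination.

Chao1 (bias-corrected), Shannon (natural log), Bray-Curtis dissimilarity
and classical PCoA — thin, validated wrappers over scikit-bio and scipy,
operating on plain abundance vectors / distance matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis as _braycurtis
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _chao1
from skbio.stats.ordination import pcoa as _pcoa


def _clean_counts(counts) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or (arr < 0).any():
        raise ValueError("counts must be a nonempty non-negative vector")
    if arr.sum() == 0:
        raise ValueError("all-zero abundance vector")
    return arr


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1))."""
    arr = _clean_counts(counts)
    return float(_chao1(arr.astype(int), bias_corrected=True))


def shannon(counts) -> float:
    """Shannon entropy -sum p_i ln p_i (natural log, zeros skipped)."""
    arr = _clean_counts(counts)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors all-zero")
    return float(_braycurtis(x, y))


def beta_matrix(table) -> np.ndarray:
    """All-pairs Bray-Curtis over the rows of a samples x features matrix."""
    m = np.asarray(table, dtype=float)
    n = m.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(m[i], m[j])
    return out


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates plus eigenvalue spectrum."""

    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def pcoa(distances, n_axes: int | None = None) -> OrdinationResult:
    """Classical (Gower-centered) principal coordinates analysis.

    Axes with non-positive eigenvalues are dropped; negative eigenvalues
    remain visible in the reported spectrum.
    """
    dm = np.asarray(distances, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.allclose(dm, 0):
        n = dm.shape[0]
        k = n_axes or 1
        return OrdinationResult(
            coordinates=np.zeros((n, k)),
            eigenvalues=np.zeros(n),
            proportion_explained=np.zeros(k),
        )
    ids = [str(i) for i in range(dm.shape[0])]
    res = _pcoa(DistanceMatrix(dm, ids), method="eigh")
    eigvals = np.asarray(res.eigvals, dtype=float)
    coords = np.asarray(res.samples, dtype=float)
    prop = np.asarray(res.proportion_explained, dtype=float)
    positive = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    coords = coords[:, positive]
    prop = prop[positive]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    return OrdinationResult(
        coordinates=coords, eigenvalues=eigvals, proportion_explained=prop
    )
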