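"""Spatial principal components of genotypes.

sPCA axes jointly maximize genetic variance and spatial autocorrelation:
with X the column-centered allele-dosage matrix (n x p) and W the
row-normalized weight matrix of a connection network over the sampling
coordinates, the analysis eigen-decomposes

    H = (1 / 2n) X^T (W + W^T) X

whose positive eigenvalues capture cline-like (globally autocorrelated)
structure and negative ones local (neighbour-contrast) structure.  The
global significance test permutes the assignment of coordinates to
individuals and compares the largest positive eigenvalue with its
permutation distribution.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .genotypes import GenotypeTable
from .popgen import one_hot_dosage

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SpatialScores:
    coordinates: pd.DataFrame  # individual, lon, lat (after any jitter)
    edges: list[tuple[int, int]]
    eigenvalues: np.ndarray  # signed, descending
    scores: pd.DataFrame  # individuals x axes (leading positive axes)
    global_stat: float
    p_value: float
    n_perm: int


def knn_network(coords: np.ndarray, k: int = 5) -> np.ndarray:
    """Symmetrized k-nearest-neighbour adjacency (0/1) matrix."""
    n = coords.shape[0]
    if n <= 1:
        return np.zeros((n, n))
    k_eff = min(k, n - 1)
    if k_eff <= 0:
        return np.zeros((n, n))
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_eff + 1)
    A = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:
            A[i, j] = A[j, i] = 1.0
    return A


def _row_normalize(A: np.ndarray) -> np.ndarray:
    rs = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(rs > 0, A / np.maximum(rs, 1e-300), 0.0)
    return W


def _lagged_eigs(X: np.ndarray, W: np.ndarray):
    """Signed eigenvalues (descending) and p-space eigenvectors of H via
    the n x n reduction (H shares its nonzero spectrum with the small
    matrix built from X's thin SVD)."""
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    M = 0.5 * (W + W.T)
    S = np.diag(s)
    C = (S @ U.T @ M @ U @ S) / n
    C = 0.5 * (C + C.T)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    axes = Vt.T @ vecs  # p-space directions
    return vals, axes


def spca_rtest(
    table: GenotypeTable,
    coordinates: pd.DataFrame,
    k_neighbors: int = 5,
    n_perm: int = 1000,
    n_axes: int = 3,
    seed: int | None = None,
) -> SpatialScores:
    """sPCA of a genotype table with a global Monte-Carlo test.

    ``coordinates`` must carry lon/lat (decimal degrees) indexed or
    columned by individual.  Coincident coordinates are jittered (seeded).
    The global statistic is the largest positive eigenvalue of the
    spatially lagged covariance; its p-value is the proportion of
    coordinate-permutation replicates whose statistic is at least the
    observed value, with the (b+1)/(m+1) correction.
    """
    rng = np.random.default_rng(seed)
    coords = coordinates.copy()
    if "individual" in coords.columns:
        coords = coords.set_index("individual")
    coords = coords.loc[table.individuals, ["lon", "lat"]].astype(float)
    xy = coords.to_numpy()
    if len(np.unique(xy, axis=0)) < len(xy):
        logger.warning("coincident coordinates; applying seeded jitter")
        xy = xy + rng.uniform(-1e-4, 1e-4, size=xy.shape)
        coords.loc[:, ["lon", "lat"]] = xy

    X, _ = one_hot_dosage(table)
    A = knn_network(xy, k_neighbors)
    W = _row_normalize(A)
    if not A.any():
        k_scores = pd.DataFrame(np.zeros((len(xy), 1)), index=table.individuals)
        return SpatialScores(coords.reset_index(), [], np.zeros(1), k_scores, 0.0, 1.0, n_perm)

    vals, axes = _lagged_eigs(X, W)
    stat = float(max(vals[0], 0.0))
    n = X.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Wp = W[np.ix_(perm, perm)]
        pv, _ = _lagged_eigs(X, Wp)
        if max(pv[0], 0.0) >= stat - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    n_axes = min(n_axes, axes.shape[1])
    scores = pd.DataFrame(
        X @ axes[:, :n_axes],
        index=table.individuals,
        columns=[f"sPC{i + 1}" for i in range(n_axes)],
    )
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j] > 0]
    return SpatialScores(coords.reset_index(), edges, vals, scores, stat, p, n_perm)
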