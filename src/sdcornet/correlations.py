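"""Pairwise association matrices: distance, Pearson, Spearman, signed
distance correlation and mutual information.

Distance correlation between two genes is computed from their sample-wise
absolute-difference matrices: each gene's n x n matrix of |x_h - x_k| is
double-centered, and the correlation is the non-negative square root of the
Pearson correlation between the two centered matrices.  It is zero iff the
expression vectors are independent, and detects nonlinear as well as linear
dependence.  The signed variant multiplies it by the sign of the ordinary
Pearson correlation of the same pair, restoring the direction of
association that the (always non-negative) distance correlation discards.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "CorrelationMatrix",
    "CenteredDistanceProfile",
    "expression_distance_matrix",
    "double_center",
    "distance_correlation_matrix",
    "pearson_correlation_matrix",
    "spearman_correlation_matrix",
    "signed_distance_correlation",
    "mutual_information_matrix",
    "compute_correlation",
    "METHODS",
]

METHODS = ("distance", "pearson", "spearman", "signed_distance", "mutual_information")

_DEGENERATE_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric m x m association values tagged with their method."""

    values: np.ndarray
    method: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        m = len(self.gene_ids)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match gene_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")


@dataclass
class CenteredDistanceProfile:
    """Double-centered expression-distance matrix of a single gene."""

    values: np.ndarray
    gene_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.abs(self.values.sum(axis=0)).max() > 1e-9:
            raise ValueError("column sums not zero after double centering")
        if np.abs(self.values.sum(axis=1)).max() > 1e-9:
            raise ValueError("row sums not zero after double centering")


def expression_distance_matrix(row: np.ndarray) -> np.ndarray:
    """n x n matrix of absolute expression differences |x_h - x_k|."""
    row = np.asarray(row, dtype=float).ravel()
    if row.size < 2:
        raise ValueError("need at least 2 samples")
    return np.abs(row[:, None] - row[None, :])


def double_center(Ytilde: np.ndarray, gene_id: str = "") -> CenteredDistanceProfile:
    """Subtract row and column means, add the grand mean."""
    Y = np.asarray(Ytilde, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
        raise ValueError("expected a square matrix")
    rm = Y.mean(axis=1, keepdims=True)
    cm = Y.mean(axis=0, keepdims=True)
    return CenteredDistanceProfile(Y - rm - cm + Y.mean(), gene_id)


def _centered_profiles(values: np.ndarray) -> np.ndarray:
    """Flattened double-centered distance matrices, one row per gene."""
    m, n = values.shape
    out = np.empty((m, n * n))
    for i in range(m):
        Y = expression_distance_matrix(values[i])
        rm = Y.mean(axis=1, keepdims=True)
        cm = Y.mean(axis=0, keepdims=True)
        out[i] = (Y - rm - cm + Y.mean()).ravel()
    return out


def _warn_degenerate(gene_ids, degenerate: np.ndarray, what: str) -> None:
    if degenerate.any():
        names = [gene_ids[i] for i in np.flatnonzero(degenerate)]
        shown = ", ".join(names[:10]) + ("..." if len(names) > 10 else "")
        warnings.warn(
            f"{len(names)} constant gene row(s) have undefined {what}; "
            f"their correlations are set to 0: {shown}",
            RuntimeWarning,
            stacklevel=3,
        )


def distance_correlation_matrix(Mstar, block_size: int = 256) -> CorrelationMatrix:
    """All-pairs distance correlation of the rows of M*.

    The inner products of the flattened centered profiles are accumulated
    in gene blocks, so memory stays at O(block_size * n^2); results are
    independent of the block size.  Constant rows (distance variance zero)
    get correlation 0 and a warning.
    """
    values = np.asarray(Mstar.values, dtype=float)
    gene_ids = list(Mstar.gene_ids)
    m, n = values.shape
    G = np.empty((m, m))
    starts = list(range(0, m, block_size))
    blocks = {}
    for s in starts:
        blocks[s] = _centered_profiles(values[s : s + block_size])
    for si, s in enumerate(starts):
        for t in starts[si:]:
            prod = blocks[s] @ blocks[t].T
            G[s : s + block_size, t : t + block_size] = prod
            G[t : t + block_size, s : s + block_size] = prod.T
    diag = np.diag(G).copy()
    degenerate = diag <= _DEGENERATE_TOL
    _warn_degenerate(gene_ids, degenerate, "distance variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.sqrt(np.outer(diag, diag))  # sqrt(G_ii * G_jj)
        D = np.sqrt(np.clip(G, 0.0, None) / norm)
    D = np.nan_to_num(D, nan=0.0, posinf=0.0, neginf=0.0)
    D[degenerate, :] = 0.0
    D[:, degenerate] = 0.0
    idx = np.flatnonzero(~degenerate)
    D[idx, idx] = 1.0
    np.clip(D, 0.0, 1.0, out=D)
    return CorrelationMatrix((D + D.T) / 2.0, "distance", gene_ids)


def pearson_correlation_matrix(Mstar) -> CorrelationMatrix:
    """Row-wise Pearson correlations; constant rows get 0 with a warning."""
    values = np.asarray(Mstar.values, dtype=float)
    gene_ids = list(Mstar.gene_ids)
    sd = values.std(axis=1)
    degenerate = sd <= _DEGENERATE_TOL
    _warn_degenerate(gene_ids, degenerate, "variance")
    safe = values.copy()
    safe[degenerate] = np.arange(values.shape[1])  # placeholder, zeroed below
    P = np.corrcoef(safe)
    P[degenerate, :] = 0.0
    P[:, degenerate] = 0.0
    idx = np.flatnonzero(~degenerate)
    P[idx, idx] = 1.0
    np.clip(P, -1.0, 1.0, out=P)
    return CorrelationMatrix((P + P.T) / 2.0, "pearson", gene_ids)


def spearman_correlation_matrix(Mstar) -> CorrelationMatrix:
    """Pearson correlation of within-row average ranks."""
    values = np.asarray(Mstar.values, dtype=float)
    ranks = rankdata(values, axis=1, method="average")

    class _R:
        pass

    R = _R()
    R.values = ranks
    R.gene_ids = list(Mstar.gene_ids)
    P = pearson_correlation_matrix(R)
    return CorrelationMatrix(P.values, "spearman", list(Mstar.gene_ids))


def signed_distance_correlation(
    D: CorrelationMatrix, P: CorrelationMatrix
) -> CorrelationMatrix:
    """S = sign(P) * D with sign(0) = 0."""
    if D.method != "distance" or P.method != "pearson":
        raise ValueError("expected a distance and a pearson matrix")
    if D.gene_ids != P.gene_ids:
        raise ValueError("gene sets of D and P differ")
    S = np.sign(P.values) * D.values
    return CorrelationMatrix(S, "signed_distance", list(D.gene_ids))


def _equal_frequency_labels(row: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin labels 0..n_bins-1 with bin sizes as equal as possible.

    Ties are split by sample order so every bin holds floor(n/b) or
    ceil(n/b) observations.
    """
    n = row.size
    r = rankdata(row, method="ordinal") - 1
    return (r * n_bins) // n


def mutual_information_matrix(Mstar, n_bins: int | None = None) -> CorrelationMatrix:
    """Plug-in mutual information (natural log) after equal-frequency
    discretization of each gene's expression vector.

    ``n_bins`` defaults to floor(sqrt(n)).  Setting ``n_bins = n`` gives the
    degenerate one-observation-per-bin estimator, in which every pair scores
    the same maximal value log(n).
    """
    values = np.asarray(Mstar.values, dtype=float)
    gene_ids = list(Mstar.gene_ids)
    m, n = values.shape
    if n_bins is None:
        n_bins = max(2, math.floor(math.sqrt(n)))
    if not (2 <= n_bins <= n):
        raise ValueError(f"n_bins must be in [2, n={n}], got {n_bins}")
    labels = np.vstack([_equal_frequency_labels(values[i], n_bins) for i in range(m)])
    marg = np.vstack([np.bincount(labels[i], minlength=n_bins) for i in range(m)])
    I = np.zeros((m, m))
    b = n_bins
    for i in range(m):
        li = labels[i] * b
        for j in range(i, m):
            joint = np.bincount(li + labels[j], minlength=b * b).astype(float)
            nz = joint > 0
            pij = joint[nz] / n
            pi = marg[i][(np.flatnonzero(nz) // b)] / n
            pj = marg[j][(np.flatnonzero(nz) % b)] / n
            mi = float(np.sum(pij * np.log(pij / (pi * pj))))
            I[i, j] = I[j, i] = max(mi, 0.0)
    return CorrelationMatrix(I, "mutual_information", gene_ids)


def compute_correlation(Mstar, method: str, mi_bins: int | None = None) -> CorrelationMatrix:
    """Dispatch on method name; ``signed_distance`` combines D and P."""
    if method == "distance":
        return distance_correlation_matrix(Mstar)
    if method == "pearson":
        return pearson_correlation_matrix(Mstar)
    if method == "spearman":
        return spearman_correlation_matrix(Mstar)
    if method == "signed_distance":
        D = distance_correlation_matrix(Mstar)
        P = pearson_correlation_matrix(Mstar)
        return signed_distance_correlation(D, P)
    if method == "mutual_information":
        return mutual_information_matrix(Mstar, mi_bins)
    raise ValueError(f"unknown method {method!r}")
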