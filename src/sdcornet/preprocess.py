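"""Low-expression masking and quantile normalization.

The raw matrix M is cleaned in two steps: within each sample (column) the
lowest ``fraction`` of values is masked as unreliable, then the unmasked
values are quantile-normalized across samples so every column shares one
empirical distribution, and finally the masked entries are set to the
global minimum of the raw matrix.  The default fraction is 0.2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionMatrix

__all__ = [
    "PreprocessedMatrix",
    "low_expression_mask",
    "quantile_normalize",
    "preprocess",
]


@dataclass
class PreprocessedMatrix:
    """Normalized matrix M* plus the mask of floored low-expression entries."""

    values: np.ndarray
    mask: np.ndarray
    floor_value: float
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.mask.any() and not np.allclose(
            self.values[self.mask], self.floor_value
        ):
            raise ValueError("masked entries must all equal floor_value")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def low_expression_mask(M: ExpressionMatrix, fraction: float) -> np.ndarray:
    """Boolean mask of the floor(fraction * m) smallest entries per column.

    Ties at the cutoff are broken by row order (stable sort), so exactly the
    same number of entries is masked in every sample.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    m, n = M.values.shape
    k = math.floor(fraction * m)
    mask = np.zeros((m, n), dtype=bool)
    if k == 0:
        return mask
    for j in range(n):
        order = np.argsort(M.values[:, j], kind="stable")
        mask[order[:k], j] = True
    return mask


def quantile_normalize(M: ExpressionMatrix, mask: np.ndarray) -> PreprocessedMatrix:
    """Quantile-normalize the unmasked entries of each column.

    Every column must carry the same number of unmasked entries.  The
    reference distribution is the rank-wise mean of the column-sorted
    unmasked values; tied raw values within a column receive the mean of the
    reference values of their tied ranks.  Masked entries are then set to
    the minimum of the raw matrix.
    """
    mask = np.asarray(mask, dtype=bool)
    values = M.values
    m, n = values.shape
    if mask.shape != (m, n):
        raise ValueError("mask shape does not match matrix")
    counts = (~mask).sum(axis=0)
    if len(set(counts.tolist())) != 1:
        raise ValueError(
            f"unequal unmasked counts per column: {sorted(set(counts.tolist()))}"
        )
    u = int(counts[0])
    if u == 0:
        raise ValueError("all entries masked")
    sorted_cols = np.empty((u, n))
    for j in range(n):
        sorted_cols[:, j] = np.sort(values[~mask[:, j], j])
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    floor_value = float(values.min())
    for j in range(n):
        keep = ~mask[:, j]
        col = values[keep, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(u)
        assigned[order] = reference
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        cnt = np.bincount(inv)
        out[keep, j] = (sums / cnt)[inv]
        out[mask[:, j], j] = floor_value
    return PreprocessedMatrix(out, mask, floor_value, list(M.gene_ids), list(M.sample_ids))


def preprocess(
    M: ExpressionMatrix,
    fraction: float = 0.2,
    normalize_unmasked_only: bool = True,
) -> PreprocessedMatrix:
    """Mask the lowest ``fraction`` per sample, quantile-normalize, floor.

    By default only unmasked entries enter the normalization (masked values
    are ignored before the normalization step).  With
    ``normalize_unmasked_only=False`` all entries are normalized first and
    the masked ones are overwritten with the raw global minimum afterwards.
    """
    mask = low_expression_mask(M, fraction)
    if normalize_unmasked_only:
        return quantile_normalize(M, mask)
    full = quantile_normalize(M, np.zeros_like(mask))
    out = full.values.copy()
    floor_value = float(M.values.min())
    out[mask] = floor_value
    return PreprocessedMatrix(out, mask, floor_value, list(M.gene_ids), list(M.sample_ids))
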