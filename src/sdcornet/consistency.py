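"""Self-consistency threshold selection.

The idea: a good hard threshold should yield networks that are stable under
resampling of the samples.  Two overlapping column subsets of the raw
matrix are drawn (each of size floor(3n/4), sharing floor(n/2) samples, so
about a third of each subset differs), each subset is preprocessed and
correlated independently, and the two networks obtained at a threshold
theta are compared with a corrected edge-similarity: the Jaccard index of
the edge sets adjusted by beta, the overlap expected if both graphs were
configuration-type random graphs on permuted degree sequences.  Averaging
the similarity over repetitions gives s(theta); subtracting the edge
density of the full-data network gives Score(theta), and the selected
threshold maximizes that score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correlations import compute_correlation
from .dataio import ExpressionMatrix
from .netbuild import UnweightedNetwork
from .preprocess import preprocess

__all__ = [
    "SplitPlan",
    "SimilarityResult",
    "ConsistencyProfile",
    "make_split_plan",
    "expected_overlap_beta",
    "corrected_edge_similarity",
    "consistency_profile",
    "select_threshold",
    "default_theta_grid",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_theta_grid(
    lo: float = 0.0, hi: float = 0.99, step: float = 0.01
) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclass(frozen=True)
class SplitPlan:
    """Two overlapping sample-index subsets of equal size."""

    indices_a: np.ndarray
    indices_b: np.ndarray
    shared_count: int


@dataclass(frozen=True)
class SimilarityResult:
    similarity: float
    beta: float
    intersection: int
    union: int


@dataclass
class ConsistencyProfile:
    """Per-threshold similarity s(theta), full-network density and score."""

    thetas: np.ndarray
    s_values: np.ndarray
    densities: np.ndarray
    scores: np.ndarray
    n_repetitions: int
    seed: int | None
    method: str = ""

    def __post_init__(self) -> None:
        for name in ("thetas", "s_values", "densities", "scores"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.allclose(self.scores, self.s_values - self.densities):
            raise ValueError("scores must equal s_values - densities")


def make_split_plan(
    n: int,
    rng,
    subset_fraction: float = 0.75,
    shared_fraction: float = 0.5,
) -> SplitPlan:
    """Draw two subsets of size floor(subset_fraction * n) sharing
    floor(shared_fraction * n) uniformly chosen samples."""
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = _as_rng(rng)
    size = int(np.floor(subset_fraction * n))
    shared = int(np.floor(shared_fraction * n))
    uniq = size - shared
    if uniq < 0 or 2 * uniq + shared > n:
        raise ValueError(
            f"infeasible split: subset size {size}, shared {shared}, n={n}"
        )
    perm = rng.permutation(n)
    shared_idx = perm[:shared]
    a_uniq = perm[shared : shared + uniq]
    b_uniq = perm[shared + uniq : shared + 2 * uniq]
    return SplitPlan(
        np.concatenate([shared_idx, a_uniq]),
        np.concatenate([shared_idx, b_uniq]),
        shared,
    )


def _beta_term(er: np.ndarray, ec: np.ndarray, n_edges: int, d_other: np.ndarray) -> float:
    """|E1| * sum_{(u,v) in E1} d(u)d(v) / sum_{u} sum_{v != u} d(u)d(v).

    The denominator runs over ordered node pairs, which caps each term at
    |E_i|/2 and hence beta at (|E1|+|E2|)/2 — exactly what keeps the
    corrected similarity within [-1/3, 1].
    """
    if n_edges == 0:
        return 0.0
    den = d_other.sum() ** 2 - (d_other**2).sum()
    if den <= 0:
        return 0.0
    num = float((d_other[er] * d_other[ec]).sum())
    return n_edges * num / den


def _beta_arrays(
    e1r, e1c, e2r, e2c, d1, d2, rng, halve: bool = False
) -> float:
    d1p = rng.permutation(d1)
    d2p = rng.permutation(d2)
    beta = _beta_term(e1r, e1c, e1r.size, d2p) + _beta_term(e2r, e2c, e2r.size, d1p)
    return beta / 2.0 if halve else beta


def _edges_arrays(net: UnweightedNetwork) -> tuple[np.ndarray, np.ndarray]:
    if net.edges:
        arr = np.array(sorted(net.edges), dtype=int)
        return arr[:, 0], arr[:, 1]
    return np.empty(0, dtype=int), np.empty(0, dtype=int)


def expected_overlap_beta(
    G1: UnweightedNetwork, G2: UnweightedNetwork, rng, halve: bool = False
) -> float:
    """Expected edge overlap of G1 and G2 under a configuration-type model.

    The degree sequences of both graphs are randomly permuted over the node
    set; each directional term weights the other graph's permuted degree
    products along this graph's edges, normalized by the product sum over
    all ordered node pairs; for equal edge counts the sum of the two terms
    is the average expected overlap in the two directions.  A graph with no
    edges contributes 0.  With ``halve=True`` the two directional terms are
    averaged instead of summed.
    """
    if G1.node_ids != G2.node_ids:
        raise ValueError("networks must share an identical node set")
    rng = _as_rng(rng)
    e1r, e1c = _edges_arrays(G1)
    e2r, e2c = _edges_arrays(G2)
    return _beta_arrays(e1r, e1c, e2r, e2c, G1.degrees(), G2.degrees(), rng, halve)


def corrected_edge_similarity(
    G1: UnweightedNetwork,
    G2: UnweightedNetwork,
    rng,
    beta: float | None = None,
    halve_beta: bool = False,
) -> SimilarityResult:
    """(|E1 ∩ E2| - beta) / (|E1 ∪ E2| + beta), in [-1/3, 1].

    ``beta`` may be supplied (e.g. 0 to recover the plain Jaccard index);
    otherwise it is drawn via :func:`expected_overlap_beta`.
    """
    if G1.node_ids != G2.node_ids:
        raise ValueError("networks must share an identical node set")
    inter = len(G1.edges & G2.edges)
    union = len(G1.edges | G2.edges)
    if beta is None:
        beta = expected_overlap_beta(G1, G2, rng, halve=halve_beta)
    if union + beta == 0:
        warnings.warn("both edge sets empty; similarity defined as 0", RuntimeWarning)
        return SimilarityResult(0.0, float(beta), inter, union)
    return SimilarityResult((inter - beta) / (union + beta), float(beta), inter, union)


def _degrees_from_bool(e: np.ndarray, r: np.ndarray, c: np.ndarray, m: int) -> np.ndarray:
    return (
        np.bincount(r, weights=e.astype(float), minlength=m)
        + np.bincount(c, weights=e.astype(float), minlength=m)
    )


def consistency_profile(
    M: ExpressionMatrix,
    method: str = "signed_distance",
    thetas=None,
    n_repetitions: int = 25,
    seed=0,
    mask_fraction: float = 0.2,
    mi_bins: int | None = None,
    subset_fraction: float = 0.75,
    shared_fraction: float = 0.5,
    preprocess_subsets: bool = True,
    halve_beta: bool = False,
) -> ConsistencyProfile:
    """Score(theta) = mean corrected similarity of split networks - density.

    For each repetition one split is drawn and reused for every theta; each
    submatrix is preprocessed independently by default (set
    ``preprocess_subsets=False`` to slice the preprocessed full matrix
    instead).  The density term always comes from the full-data network.
    Deterministic for a fixed seed.
    """
    if thetas is None:
        thetas = default_theta_grid()
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("empty theta grid")
    if np.any(np.diff(thetas) < 0):
        raise ValueError("thetas must be sorted ascending")
    if n_repetitions < 1:
        raise ValueError("need at least one repetition")

    m, n = M.values.shape
    full_star = preprocess(M, mask_fraction)
    C_full = compute_correlation(full_star, method, mi_bins)
    r_idx, c_idx = np.triu_indices(m, k=1)
    full_vals = C_full.values[r_idx, c_idx]
    npairs = full_vals.size
    densities = np.array([(full_vals >= t).sum() / npairs for t in thetas])

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_repetitions)
    sims = np.empty((n_repetitions, thetas.size))
    n_empty = 0
    for rep in range(n_repetitions):
        rng = np.random.default_rng(children[rep])
        plan = make_split_plan(n, rng, subset_fraction, shared_fraction)
        halves = []
        for idx in (plan.indices_a, plan.indices_b):
            if preprocess_subsets:
                sub = M.subset_samples(idx)
                star = preprocess(sub, mask_fraction)
            else:
                star = _SlicedMatrix(full_star.values[:, idx], M.gene_ids)
            C = compute_correlation(star, method, mi_bins)
            halves.append(C.values[r_idx, c_idx])
        v1, v2 = halves
        for t_i, theta in enumerate(thetas):
            e1 = v1 >= theta
            e2 = v2 >= theta
            inter = int(np.count_nonzero(e1 & e2))
            union = int(np.count_nonzero(e1 | e2))
            d1 = _degrees_from_bool(e1, r_idx, c_idx, m)
            d2 = _degrees_from_bool(e2, r_idx, c_idx, m)
            beta = _beta_arrays(
                r_idx[e1], c_idx[e1], r_idx[e2], c_idx[e2], d1, d2, rng, halve_beta
            )
            if union + beta == 0:
                n_empty += 1
                sims[rep, t_i] = 0.0
            else:
                sims[rep, t_i] = (inter - beta) / (union + beta)
    if n_empty:
        warnings.warn(
            f"{n_empty} repetition/theta combinations produced two empty "
            "networks; their similarity was set to 0",
            RuntimeWarning,
        )
    s_values = sims.mean(axis=0)
    return ConsistencyProfile(
        thetas,
        s_values,
        densities,
        s_values - densities,
        n_repetitions,
        seed if isinstance(seed, int) else None,
        method,
    )


class _SlicedMatrix:
    """Minimal matrix-like view used when subsets reuse the full M*."""

    def __init__(self, values: np.ndarray, gene_ids) -> None:
        self.values = values
        self.gene_ids = list(gene_ids)


def select_threshold(profile: ConsistencyProfile) -> tuple[float, float, float]:
    """Argmax of Score(theta); ties broken toward the larger threshold."""
    scores = profile.scores
    if scores.size == 0:
        raise ValueError("empty profile")
    best = scores.max()
    if np.allclose(scores, scores[0]) and scores.size > 1:
        warnings.warn("all scores equal; returning the largest theta", RuntimeWarning)
    idx = int(np.flatnonzero(scores == best).max())
    return float(profile.thetas[idx]), float(scores[idx]), float(profile.densities[idx])
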