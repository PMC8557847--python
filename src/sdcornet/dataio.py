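"""File formats and synthetic data.

Expression matrices are plain TSV, genes in rows, samples in columns, a
header row of sample IDs and a first column of gene IDs (gzip accepted
transparently).  Interaction scores follow the STRING
``protein.links.detailed`` dialect: whitespace-delimited, two ID columns
followed by integer evidence-channel scores in [0, 1000].  Edge lists are
two-column TSV with a sidecar node file so isolated genes survive a
round-trip.

The synthetic generator builds modular expression data: each module has one
latent profile, member genes follow it linearly, anti-correlated (sign
flipped) or through a monotone-free quadratic transform, plus independent
background genes.  A paired truth table records the within-module pairs so
that recovered networks can be scored exactly.
"""
from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import UnweightedNetwork

__all__ = [
    "ExpressionMatrix",
    "InteractionScoreTable",
    "SyntheticTruth",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_interaction_scores",
    "write_edge_list",
    "read_edge_list",
    "write_correlation_matrix",
    "read_correlation_matrix",
    "generate_synthetic_expression",
    "generate_synthetic_interactions",
]


@dataclass
class ExpressionMatrix:
    """Raw expression values, m genes x n samples, with unique labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 genes and 2 samples, got {m} x {n}")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, indices) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, indices],
            self.gene_ids,
            [self.sample_ids[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples TSV with sample header and gene-ID column.

    Non-numeric cells raise a parse error naming the offending gene and
    sample; duplicated IDs raise a validation error.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = [h for h in header[1:] if h != ""]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample IDs in header")
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, header=0)
    raw.columns = sample_ids  # undo pandas' silent dedup of repeated headers
    gene_ids = [str(g) for g in raw.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"{path}: duplicate gene IDs")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}: {raw.iat[i, j]!r}"
        )
    return ExpressionMatrix(numeric.to_numpy(dtype=float), gene_ids, sample_ids)


def write_expression_matrix(matrix, path, delimiter: str = "\t") -> None:
    """Write a matrix-like object (ExpressionMatrix or preprocessed) as TSV."""
    df = pd.DataFrame(
        np.asarray(matrix.values, dtype=float),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )
    df.to_csv(path, sep=delimiter)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionScoreTable:
    """Unordered gene pairs with integer per-channel confidence scores."""

    records: dict[tuple[str, str], dict[str, int]]
    channel_names: list[str]

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], dict[str, int]] = {}
        for pair, channels in self.records.items():
            a, b = map(str, pair)
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            for ch, s in channels.items():
                if not (0 <= int(s) <= 1000):
                    raise ValueError(f"score {s} for pair ({a}, {b}) channel {ch} outside [0, 1000]")
            clean[_pair_key(a, b)] = {str(c): int(s) for c, s in channels.items()}
        self.records = clean
        self.channel_names = [str(c) for c in self.channel_names]

    def __len__(self) -> int:
        return len(self.records)

    def channels_for(self, a: str, b: str) -> dict[str, int]:
        """Channel map for an unordered pair; absent channels default to 0."""
        rec = self.records.get(_pair_key(str(a), str(b)), {})
        return {c: rec.get(c, 0) for c in self.channel_names}


def read_interaction_scores(path) -> InteractionScoreTable:
    """Read a STRING ``protein.links.detailed``-style whitespace table.

    Pairs listed in both orders are de-duplicated; conflicting duplicate
    scores are merged by elementwise max.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected two ID columns plus at least one score column")
    channels = [str(c) for c in df.columns[2:]]
    records: dict[tuple[str, str], dict[str, int]] = {}
    ids_a = df.iloc[:, 0].astype(str).to_numpy()
    ids_b = df.iloc[:, 1].astype(str).to_numpy()
    scores = df.iloc[:, 2:].to_numpy()
    if not np.issubdtype(scores.dtype, np.number):
        raise ValueError(f"{path}: non-numeric score entries")
    if (scores < 0).any() or (scores > 1000).any():
        bad = np.argwhere((scores < 0) | (scores > 1000))[0]
        raise ValueError(
            f"{path}: score {scores[bad[0], bad[1]]} outside [0, 1000] at line {bad[0] + 2}"
        )
    for a, b, row in zip(ids_a, ids_b, scores):
        key = _pair_key(a, b)
        new = {c: int(s) for c, s in zip(channels, row)}
        if key in records:
            prev = records[key]
            records[key] = {c: max(prev.get(c, 0), new[c]) for c in channels}
        else:
            records[key] = new
    return InteractionScoreTable(records, channels)


def write_edge_list(net: UnweightedNetwork, path, node_path=None) -> None:
    """Two-column TSV, one unordered edge per line (smaller ID first),
    lexicographically sorted; all node IDs go to a sidecar node file."""
    path = Path(path)
    if node_path is None:
        node_path = path.with_name(path.name + ".nodes")
    lines = sorted(net.edge_ids())
    with open(path, "wt") as fh:
        for a, b in lines:
            fh.write(f"{a}\t{b}\n")
    with open(node_path, "wt") as fh:
        for g in net.node_ids:
            fh.write(f"{g}\n")


def read_edge_list(path, node_path=None) -> UnweightedNetwork:
    path = Path(path)
    if node_path is None:
        node_path = path.with_name(path.name + ".nodes")
    with open(node_path, "rt") as fh:
        node_ids = [line.strip() for line in fh if line.strip()]
    pairs = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")
            pairs.append((a, b))
    return UnweightedNetwork.from_id_pairs(node_ids, pairs)


def write_correlation_matrix(C, path, delimiter: str = "\t") -> None:
    """Persist a correlation matrix as (optionally gzipped) TSV with the
    method recorded on a leading ``#method=`` comment line."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    df = pd.DataFrame(C.values, index=C.gene_ids, columns=C.gene_ids)
    with opener(path, "wt") as fh:
        fh.write(f"#method={C.method}\n")
        df.to_csv(fh, sep=delimiter)


def read_correlation_matrix(path, delimiter: str = "\t"):
    from .correlations import CorrelationMatrix

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline().strip()
        if not first.startswith("#method="):
            raise ValueError(f"{path}: missing #method= header line")
        method = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep=delimiter, index_col=0)
    return CorrelationMatrix(df.to_numpy(dtype=float), method, [str(g) for g in df.index])


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic expression matrix.

    ``module_assignment`` maps gene -> module index (``None`` = background),
    ``dependency_kind`` maps gene -> linear | nonlinear | anti | background,
    ``true_pairs`` is exactly the set of within-module unordered pairs.
    """

    module_assignment: dict[str, int | None]
    dependency_kind: dict[str, str]
    true_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = set()
        by_module: dict[int, list[str]] = {}
        for g, k in self.module_assignment.items():
            if k is not None:
                by_module.setdefault(k, []).append(g)
        for members in by_module.values():
            for a, b in itertools.combinations(sorted(members), 2):
                expected.add(_pair_key(a, b))
        self.true_pairs = {_pair_key(a, b) for a, b in self.true_pairs} or expected
        if self.true_pairs != expected:
            raise ValueError("true_pairs must be exactly the within-module pairs")


def generate_synthetic_expression(
    n_modules: int = 2,
    genes_per_module: int = 20,
    n_background: int = 160,
    n_samples: int = 50,
    noise_sd: float = 0.1,
    frac_nonlinear: float = 0.0,
    frac_anti: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Modular expression data with known coexpressed pairs.

    Each module k has a latent profile z_k ~ N(0, 1) i.i.d. across samples.
    A linear gene is z_k + eps, an anti gene is -z_k + eps and a nonlinear
    gene is the standardized square of the centered profile plus eps, with
    eps ~ N(0, noise_sd^2).  Background genes are i.i.d. standard normal.
    Deterministic for a fixed seed.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not (0 <= frac_nonlinear <= 1 and 0 <= frac_anti <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if frac_nonlinear + frac_anti > 1:
        raise ValueError("frac_nonlinear + frac_anti must be <= 1")
    m = n_modules * genes_per_module + n_background
    if m == 0:
        raise ValueError("no genes requested: zero modules and zero background")
    if m < 2 or n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    rng = np.random.default_rng(seed)
    rows, gene_ids = [], []
    assignment: dict[str, int | None] = {}
    kinds: dict[str, str] = {}
    for k in range(n_modules):
        z = rng.standard_normal(n_samples)
        zc = z - z.mean()
        quad = zc**2
        quad = (quad - quad.mean()) / quad.std()
        n_nl = int(round(frac_nonlinear * genes_per_module))
        n_anti = int(round(frac_anti * genes_per_module))
        kind_list = (
            ["nonlinear"] * n_nl
            + ["anti"] * n_anti
            + ["linear"] * (genes_per_module - n_nl - n_anti)
        )
        for idx, kind in enumerate(kind_list):
            gid = f"M{k}_G{idx}"
            base = {"linear": z, "anti": -z, "nonlinear": quad}[kind]
            rows.append(base + rng.normal(0.0, noise_sd, n_samples))
            gene_ids.append(gid)
            assignment[gid] = k
            kinds[gid] = kind
    for idx in range(n_background):
        gid = f"BG_G{idx}"
        rows.append(rng.standard_normal(n_samples))
        gene_ids.append(gid)
        assignment[gid] = None
        kinds[gid] = "background"
    matrix = ExpressionMatrix(np.vstack(rows), gene_ids, [f"S{j}" for j in range(n_samples)])
    truth = SyntheticTruth(assignment, kinds)
    return matrix, truth


def generate_synthetic_interactions(
    truth: SyntheticTruth,
    score_high: int = 900,
    score_low: int = 150,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> InteractionScoreTable:
    """A STRING-like single-channel table: true pairs score ``score_high``
    and a ``flip_rate`` fraction of random non-pairs score ``score_low``."""
    if not (0 <= score_low < score_high <= 1000):
        raise ValueError("need 0 <= score_low < score_high <= 1000")
    if not (0 <= flip_rate <= 1):
        raise ValueError("flip_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_assignment)
    all_pairs = [_pair_key(a, b) for a, b in itertools.combinations(genes, 2)]
    non_pairs = [p for p in all_pairs if p not in truth.true_pairs]
    records = {p: {"combined": int(score_high)} for p in sorted(truth.true_pairs)}
    n_flip = int(round(flip_rate * len(non_pairs)))
    if n_flip:
        chosen = rng.choice(len(non_pairs), size=n_flip, replace=False)
        for idx in sorted(chosen):
            records[non_pairs[idx]] = {"combined": int(score_low)}
    return InteractionScoreTable(records, ["combined"])
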