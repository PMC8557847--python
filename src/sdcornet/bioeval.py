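"""Biological evaluation against STRING-style interaction scores.

Evidence channels (experimental, database, textmining, coexpression, ...)
are combined into a single confidence score per pair with the standard
STRING rule: scale to [0, 1], remove the random-interaction prior p from
each channel, combine as 1 - prod(1 - s_i), re-add the prior, rescale to
[0, 1000].  Three channel selections are evaluated: everything (C_total),
only the coexpression channels (C_coexpression_only), and everything
except them (C_no_coexpression).  A network's aggregate score is the mean
combined score over its edges; it is compared against random networks of
the same density to obtain fold enrichments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import InteractionScoreTable
from .netbuild import UnweightedNetwork, edge_density

__all__ = [
    "DEFAULT_PRIOR",
    "COEXPRESSION_CHANNELS",
    "ChannelCombination",
    "EvaluationReport",
    "standard_combinations",
    "combine_channels",
    "aggregate_network_score",
    "random_baseline",
    "evaluation_report",
]

DEFAULT_PRIOR = 0.041
COEXPRESSION_CHANNELS = ("coexpression", "coexpression_transferred")


@dataclass(frozen=True)
class ChannelCombination:
    name: str
    included_channels: tuple[str, ...]
    prior: float = DEFAULT_PRIOR

    def __post_init__(self) -> None:
        if not (0 <= self.prior < 1):
            raise ValueError("prior must be in [0, 1)")


def standard_combinations(
    channel_names: Sequence[str], prior: float = DEFAULT_PRIOR
) -> dict[str, ChannelCombination]:
    """The three canonical selections: all channels, coexpression-only,
    everything but coexpression."""
    channels = tuple(channel_names)
    coexpr = tuple(c for c in channels if c in COEXPRESSION_CHANNELS)
    rest = tuple(c for c in channels if c not in COEXPRESSION_CHANNELS)
    return {
        "C_total": ChannelCombination("C_total", channels, prior),
        "C_coexpression_only": ChannelCombination("C_coexpression_only", coexpr, prior),
        "C_no_coexpression": ChannelCombination("C_no_coexpression", rest, prior),
    }


def combine_channels(scores: Mapping[str, int], combo: ChannelCombination) -> float:
    """Combined confidence in [0, 1000] for one pair.

    Channels absent from ``scores`` count as 0.  If no included channel
    carries evidence above the prior the result is 0 (the prior is only
    re-added when there is evidence), so a single-channel table passes
    through unchanged.
    """
    if not combo.included_channels:
        return 0.0
    p = combo.prior
    no_evidence = 1.0
    for ch in combo.included_channels:
        s = scores.get(ch, 0) / 1000.0
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"channel {ch} score out of range: {s * 1000}")
        s_np = max(0.0, (s - p) / (1.0 - p))
        no_evidence *= 1.0 - s_np
    combined = 1.0 - no_evidence
    if combined == 0.0:
        return 0.0
    total = combined + p * (1.0 - combined)
    return 1000.0 * total


def aggregate_network_score(
    net: UnweightedNetwork, table: InteractionScoreTable, combo: ChannelCombination
) -> float:
    """Sum of combined edge scores divided by the number of edges.

    Edges absent from the table contribute 0 to the numerator but still
    count in the denominator.
    """
    if net.n_edges == 0:
        raise ValueError("aggregate score undefined for an empty network")
    total = 0.0
    for a, b in net.edge_ids():
        rec = table.records.get((a, b) if a <= b else (b, a))
        if rec is not None:
            total += combine_channels(rec, combo)
    return total / net.n_edges


def _pair_index_scores(
    node_ids: Sequence[str], table: InteractionScoreTable, combo: ChannelCombination
) -> dict[int, float]:
    """Map upper-triangle pair index -> combined score, for pairs whose both
    endpoints are in the node universe."""
    index = {g: k for k, g in enumerate(node_ids)}
    m = len(node_ids)
    out: dict[int, float] = {}
    for (a, b), rec in table.records.items():
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        i, j = (ia, ib) if ia < ib else (ib, ia)
        # linear index of (i, j) in the upper triangle
        k = i * (2 * m - i - 1) // 2 + (j - i - 1)
        out[k] = combine_channels(rec, combo)
    return out


def random_baseline(
    node_ids: Sequence[str],
    density: float,
    table: InteractionScoreTable,
    combo: ChannelCombination,
    n_networks: int = 30,
    rng=0,
) -> tuple[float, float]:
    """Mean and SD of the aggregate score over uniform random edge sets of
    the matching edge count on the same node set."""
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = len(node_ids)
    npairs = m * (m - 1) // 2
    n_edges = max(1, int(round(density * npairs)))
    lookup = _pair_index_scores(node_ids, table, combo)
    totals = np.empty(n_networks)
    for t in range(n_networks):
        chosen = rng.choice(npairs, size=n_edges, replace=False)
        totals[t] = sum(lookup.get(int(k), 0.0) for k in chosen) / n_edges
    sd = float(totals.std(ddof=1)) if n_networks > 1 else 0.0
    return float(totals.mean()), sd


@dataclass
class EvaluationReport:
    """Aggregate scores, random baselines and fold enrichments."""

    network_scores: dict[str, dict[str, float]]
    densities: dict[str, float]
    baselines: dict[tuple[int, str], tuple[float, float]]
    fold_enrichment: dict[str, dict[str, float]]
    n_random_networks: int
    combo_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, scores in self.network_scores.items():
            row = {"network": name, "density": self.densities[name]}
            for combo in self.combo_names:
                row[combo] = scores[combo]
                row[f"{combo}_fold"] = self.fold_enrichment[name][combo]
            rows.append(row)
        return pd.DataFrame(rows)


def evaluation_report(
    networks: Mapping[str, UnweightedNetwork],
    table: InteractionScoreTable,
    rng=0,
    n_networks: int = 30,
    prior: float = DEFAULT_PRIOR,
) -> EvaluationReport:
    """Score every network under all three channel combinations and compare
    against random baselines grouped by (exact) edge count."""
    networks = dict(networks)
    node_sets = {tuple(net.node_ids) for net in networks.values()}
    if len(node_sets) > 1:
        raise ValueError("all networks must share one node set")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    combos = standard_combinations(table.channel_names, prior)
    combo_names = list(combos)
    scores: dict[str, dict[str, float]] = {}
    densities: dict[str, float] = {}
    for name, net in networks.items():
        densities[name] = edge_density(net)
        scores[name] = {
            cname: aggregate_network_score(net, table, combo)
            for cname, combo in combos.items()
        }
    baselines: dict[tuple[int, str], tuple[float, float]] = {}
    any_net = next(iter(networks.values()))
    for edge_count in sorted({net.n_edges for net in networks.values()}):
        m = any_net.n_nodes
        dens = edge_count / (m * (m - 1) / 2)
        for cname, combo in combos.items():
            baselines[(edge_count, cname)] = random_baseline(
                any_net.node_ids, dens, table, combo, n_networks, rng
            )
    fold: dict[str, dict[str, float]] = {}
    for name, net in networks.items():
        fold[name] = {}
        for cname in combo_names:
            mean, _ = baselines[(net.n_edges, cname)]
            fold[name][cname] = scores[name][cname] / mean if mean > 0 else float("nan")
    return EvaluationReport(scores, densities, baselines, fold, n_networks, combo_names)
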