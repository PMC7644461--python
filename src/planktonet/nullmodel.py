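"""Erdos-Renyi null model for between-group edge enrichment.

For each empirical correlation network, 999 random G(n, m) graphs with the
same node set and edge count are drawn.  The number of edges between every
unordered pair of node labels (functional groups or ESD size classes,
self-pairs included) in the random graphs forms a null distribution; the
empirical count is called *rare* when it falls strictly below that
distribution's 2.5th percentile and *dominant* when strictly above the
97.5th, otherwise *neutral*.  Percentiles are the order statistics at ranks
``ceil(0.025 R)`` and ``ceil(0.975 R)`` of the sorted null counts (ranks 25
and 975 for R = 999); strict inequalities make boundary ties conservative.

The null keeps node identity (hence labels) but not the degree sequence: it
is a pure Erdos-Renyi model, not a configuration model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from planktonet.networks import CorrelationNetwork


@dataclass
class DominanceClassification:
    """Per label-pair verdicts against the ER null."""

    table: pd.DataFrame  # label_a, label_b, empirical, q025, q975, verdict
    n_random: int
    sign_mode: str
    grouping: str  # e.g. "functional_group" or "esd_class"


def pair_counts(net: CorrelationNetwork, labels: dict[int, str]) -> dict[tuple[str, str], int]:
    """Count edges per unordered label pair (self-pairs included)."""
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(net.edges["taxon_a"], net.edges["taxon_b"]):
        a, b = int(a), int(b)
        for t in (a, b):
            if t not in labels:
                raise ValueError(f"node {t} has no label")
        key = tuple(sorted((labels[a], labels[b])))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _index_to_pair(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices over the upper triangle (i < j) to (i, j)."""
    # row i starts at offset i*(2n-i-1)/2; invert with the closed form, then
    # correct any off-by-one from floating-point sqrt at exact boundaries
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * idx)) / 2).astype(np.int64)
    i -= idx < i * (b - i) // 2
    i += idx >= (i + 1) * (b - i - 1) // 2
    j = idx - i * (b - i) // 2 + i + 1
    return i, j


def sample_er(n_nodes: int, n_edges: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw a uniform simple graph with exactly ``n_edges`` edges (G(n, m)).

    Returns an array of shape (n_edges, 2) of node indices ``0..n_nodes-1``
    with ``i < j`` per row.
    """
    n_pairs = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= n_pairs:
        raise ValueError(f"n_edges={n_edges} outside [0, C({n_nodes},2)={n_pairs}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n_pairs, size=n_edges, replace=False)
    i, j = _index_to_pair(np.sort(idx), n_nodes)
    return np.column_stack([i, j])


def _percentile_ranks(n_random: int) -> tuple[int, int]:
    lo = math.ceil(0.025 * n_random)
    hi = math.ceil(0.975 * n_random)
    return lo, hi


def classify_pairs(
    net: CorrelationNetwork,
    labels: dict[int, str],
    n_random: int = 999,
    seed: int = 0,
    grouping: str = "functional_group",
    nodes: list[int] | None = None,
) -> DominanceClassification:
    """Classify each label pair as rare / dominant / neutral against G(n, m).

    All unordered pairs of labels present on the nodes (including self-pairs)
    are classified, whether or not they carry empirical edges.  By default
    the random graphs live on the empirical network's non-isolated node set;
    pass ``nodes`` to draw them on a larger universe (e.g. all catalogued
    taxa, isolated ones included).
    """
    if nodes is None:
        nodes = net.nodes
    else:
        nodes = sorted(int(t) for t in nodes)
        missing = set(net.nodes) - set(nodes)
        if missing:
            raise ValueError(f"explicit node set misses networked nodes: {sorted(missing)}")
    for t in nodes:
        if t not in labels:
            raise ValueError(f"node {t} has no label")
    node_labels = [labels[t] for t in nodes]
    label_set = sorted(set(node_labels))
    pairs = [
        (a, b) for i, a in enumerate(label_set) for b in label_set[i:]
    ]
    pair_index = {p: k for k, p in enumerate(pairs)}
    n = len(nodes)
    m = net.n_edges

    empirical = np.zeros(len(pairs), dtype=int)
    for key, c in pair_counts(net, labels).items():
        empirical[pair_index[key]] = c

    # label-pair id of every possible edge slot, in upper-triangle order
    n_slots = n * (n - 1) // 2
    slot_pair = np.empty(n_slots, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            slot_pair[k] = pair_index[tuple(sorted((node_labels[i], node_labels[j])))]
            k += 1

    rng = np.random.default_rng(seed)
    null = np.zeros((n_random, len(pairs)), dtype=int)
    for r in range(n_random):
        chosen = rng.choice(n_slots, size=m, replace=False)
        null[r] = np.bincount(slot_pair[chosen], minlength=len(pairs))

    lo_rank, hi_rank = _percentile_ranks(n_random)
    null_sorted = np.sort(null, axis=0)
    q025 = null_sorted[max(lo_rank - 1, 0)]
    q975 = null_sorted[min(hi_rank - 1, n_random - 1)]
    rows = []
    for kdx, (a, b) in enumerate(pairs):
        c = int(empirical[kdx])
        if m == 0:
            verdict = "neutral"
        elif c < q025[kdx]:
            verdict = "rare"
        elif c > q975[kdx]:
            verdict = "dominant"
        else:
            verdict = "neutral"
        rows.append((a, b, c, int(q025[kdx]), int(q975[kdx]), verdict))
    table = pd.DataFrame(
        rows, columns=["label_a", "label_b", "empirical", "q025", "q975", "verdict"]
    )
    return DominanceClassification(
        table=table, n_random=n_random, sign_mode=net.sign_mode, grouping=grouping
    )


def summary_network(per_mode: dict[str, DominanceClassification]) -> nx.Graph:
    """Summary graph over labels, one edge per classified pair.

    Edge attributes: ``significant`` (any non-neutral verdict), and per
    sign-mode ``verdict_<mode>`` plus ``style_<mode>`` ("solid" for dominant,
    i.e. more edges than random; "dotted" for rare, i.e. fewer).  Neutral
    pairs stay as background edges with ``significant=False``.
    """
    groupings = {c.grouping for c in per_mode.values()}
    if len(groupings) > 1:
        raise ValueError(f"mixed groupings: {sorted(groupings)}")
    g = nx.Graph()
    for mode, cls in sorted(per_mode.items()):
        for _, row in cls.table.iterrows():
            a, b = row["label_a"], row["label_b"]
            if not g.has_node(a):
                g.add_node(a)
            if not g.has_node(b):
                g.add_node(b)
            if not g.has_edge(a, b):
                g.add_edge(a, b, significant=False)
            data = g.edges[a, b]
            data[f"verdict_{mode}"] = row["verdict"]
            if row["verdict"] != "neutral":
                data["significant"] = True
                data[f"style_{mode}"] = "solid" if row["verdict"] == "dominant" else "dotted"
    return g
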