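"""Topology profiling of an undirected protein-interaction network.

Three per-node measures drive the analysis: degree (number of distinct
interaction partners), coreness (the largest K for which the node survives
K-core peeling — recursively removing all nodes of degree < K until every
remaining node has degree >= K), and the target-neighbor ratio (the fraction
of a node's partners that belong to a designated target gene set).  A target
group is then compared against the rest of the network feature-by-feature
with two-sample KS tests.

Edge attributes (physical / genetic / predicted interaction types) may be
present as a third edge-list column; all measures are type-blind and ignore
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSet, normalize_gene_id
from .stats import KSResult, ks_two_sample

__all__ = [
    "InteractionNetwork",
    "NodeTopology",
    "GroupTopologySummary",
    "read_edge_list",
    "degrees",
    "kcore_decomposition",
    "target_neighbor_ratio",
    "node_topology_table",
    "compare_groups",
    "write_group_summary_tsv",
]

logger = logging.getLogger(__name__)

FEATURES = ("degree", "coreness", "ratio")


@dataclass
class InteractionNetwork:
    """An undirected simple graph: no self-loops, no duplicate edges, each
    unordered pair stored once.  Backed by a networkx Graph."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        n_self = n_dup = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loops, collapsed %d duplicate edges", n_self, n_dup
            )
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a whitespace/tab-delimited edge list.

    Two identifier columns per line; an optional third column (interaction
    type) is accepted and ignored.  '#' lines are comments.  Identifiers are
    normalized (trimmed, case-folded) like gene-list entries so that target
    membership lookups are case-insensitive.  Self-loops are dropped and
    duplicate / reversed-duplicate edges collapsed, with counts logged.  A
    line with fewer than two or more than three tokens is a parse error
    naming the line number.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 identifier columns "
                    f"(optional third attribute), got {len(tokens)} tokens"
                )
            pairs.append((normalize_gene_id(tokens[0]), normalize_gene_id(tokens[1])))
    return InteractionNetwork.from_edges(pairs)


def degrees(network: InteractionNetwork) -> dict[str, int]:
    """Number of distinct neighbors per node; the degree sum is 2*|edges|."""
    return {node: int(deg) for node, deg in network.graph.degree()}


def kcore_decomposition(network: InteractionNetwork) -> dict[str, int]:
    """Coreness per node by iterative peeling.

    Repeatedly removes all nodes of degree < K (recomputing degrees via a
    work queue) for increasing K; a node's coreness is the largest K at which
    it is still present.  The result is independent of removal order.
    """
    deg = {node: d for node, d in network.graph.degree()}
    adjacency = {node: set(network.graph.neighbors(node)) for node in deg}
    coreness: dict[str, int] = {}
    k = 0
    remaining = set(deg)
    while remaining:
        queue = [v for v in remaining if deg[v] <= k]
        # peel everything of degree <= k; survivors form the (k+1)-core
        while queue:
            v = queue.pop()
            if v not in remaining:
                continue
            coreness[v] = k
            remaining.discard(v)
            for u in adjacency[v]:
                if u in remaining:
                    deg[u] -= 1
                    if deg[u] <= k:
                        queue.append(u)
        k += 1
    return coreness


def target_neighbor_ratio(
    network: InteractionNetwork, targets: GeneSet
) -> dict[str, Optional[float]]:
    """Fraction of each node's neighbors that are targets.

    ratio(v) = |neighbors(v) ∩ targets| / degree(v); None (undefined) for
    isolated nodes, which are excluded from group means downstream.
    """
    member = targets.members
    ratios: dict[str, Optional[float]] = {}
    for node in network.graph.nodes:
        neighbors = list(network.graph.neighbors(node))
        if not neighbors:
            ratios[node] = None
            continue
        n_target = sum(1 for u in neighbors if u in member)
        ratios[node] = n_target / len(neighbors)
    return ratios


@dataclass(frozen=True)
class NodeTopology:
    """Per-node topology record; ratio is None when degree is 0."""

    node: str
    degree: int
    coreness: int
    target_neighbor_ratio: Optional[float]


def node_topology_table(
    network: InteractionNetwork, targets: GeneSet
) -> pd.DataFrame:
    """DataFrame with columns node, degree, coreness, ratio (NaN when
    undefined), sorted by node."""
    deg = degrees(network)
    core = kcore_decomposition(network)
    ratio = target_neighbor_ratio(network, targets)
    rows = [
        {
            "node": node,
            "degree": deg[node],
            "coreness": core[node],
            "ratio": np.nan if ratio[node] is None else ratio[node],
        }
        for node in sorted(deg)
    ]
    return pd.DataFrame(rows, columns=["node", "degree", "coreness", "ratio"])


@dataclass(frozen=True)
class GroupTopologySummary:
    """Group means for the three features plus (for the target group) the KS
    comparison of targets-in-network vs all other network nodes."""

    group: str
    n: int
    mean_degree: float
    mean_coreness: float
    mean_ratio: float
    ks: dict[str, Optional[KSResult]] = field(default_factory=dict)


def _feature_vectors(table: pd.DataFrame, nodes: set[str]) -> dict[str, np.ndarray]:
    sub = table[table["node"].isin(nodes)]
    return {
        "degree": sub["degree"].to_numpy(dtype=float),
        "coreness": sub["coreness"].to_numpy(dtype=float),
        "ratio": sub["ratio"].dropna().to_numpy(dtype=float),
    }


def _summarize(group: str, feats: dict[str, np.ndarray], n: int) -> GroupTopologySummary:
    def mean(x: np.ndarray) -> float:
        return float(x.mean()) if x.size else float("nan")

    return GroupTopologySummary(
        group=group,
        n=n,
        mean_degree=mean(feats["degree"]),
        mean_coreness=mean(feats["coreness"]),
        mean_ratio=mean(feats["ratio"]),
    )


def compare_groups(
    network: InteractionNetwork,
    targets: GeneSet,
    subgroup: Optional[GeneSet] = None,
) -> list[GroupTopologySummary]:
    """Group-level topology summaries: 'all', 'targets', and optionally
    'targets&<subgroup>'.

    Means are taken over group members present in the network only (absent
    targets are counted and logged, never imputed); the ratio mean skips
    isolated nodes.  The target summary carries per-feature two-sample KS
    tests of targets-in-network vs all other network nodes; a degenerate
    complement (targets = whole network) skips the KS with a logged notice.
    """
    all_nodes = network.nodes
    in_net = targets.members & all_nodes
    absent = len(targets.members) - len(in_net)
    if absent:
        logger.info(
            "%d of %d target genes absent from the network; excluded from means",
            absent,
            len(targets.members),
        )
    if not in_net:
        raise ValueError(f"no members of {targets.name!r} are present in the network")

    table = node_topology_table(network, targets)
    summaries = [
        _summarize("all", _feature_vectors(table, all_nodes), len(all_nodes))
    ]

    target_feats = _feature_vectors(table, in_net)
    other = all_nodes - in_net
    other_feats = _feature_vectors(table, other)
    ks: dict[str, Optional[KSResult]] = {}
    for feature in FEATURES:
        a, b = target_feats[feature], other_feats[feature]
        if a.size == 0 or b.size == 0:
            logger.info("KS comparison for %s skipped: empty group", feature)
            ks[feature] = None
        else:
            ks[feature] = ks_two_sample(a, b)
    target_summary = _summarize("targets", target_feats, len(in_net))
    target_summary.ks.update(ks)
    summaries.append(target_summary)

    if subgroup is not None:
        sub_nodes = in_net & subgroup.members
        summaries.append(
            _summarize(
                f"targets&{subgroup.name}",
                _feature_vectors(table, sub_nodes),
                len(sub_nodes),
            )
        )
    return summaries


def write_group_summary_tsv(
    summaries: list[GroupTopologySummary], path: str | Path
) -> None:
    """Machine-readable group summary: one row per group, KS p-values filled
    on the target row."""
    rows = []
    for s in summaries:
        row = {
            "group": s.group,
            "n": s.n,
            "mean_degree": s.mean_degree,
            "mean_coreness": s.mean_coreness,
            "mean_ratio": s.mean_ratio,
        }
        for feature in FEATURES:
            result = s.ks.get(feature)
            row[f"ks_p_{feature}"] = "" if result is None else repr(result.p_value)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
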