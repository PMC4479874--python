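"""Network topology of CCRNs: degrees, hubs, clustering, modules.

Hubs are the proteins in the top 20% of the degree distribution (ties at the
cutoff included).  Each hub is categorised by its fraction of competitive
incident edges: cooperative (< 1/3), modest ([1/3, 2/3]), competitive (> 2/3).

Module structure comes from the Markov Cluster algorithm (MCL, inflation 2.0
by default), run per connected component.  The participation coefficient

    p_i = 1 - sum_s (k_is / k_i)^2

measures how a node's links spread over modules after modules of at most
``min_module_size`` nodes have been removed: 0 when all links stay within the
node's own module, approaching 1 for an even spread.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from ccrn.ccrn_construction import CCRN, Relation

logger = logging.getLogger(__name__)


class EdgeFilter(str, Enum):
    ALL = "all"
    COMPETITIVE_ONLY = "competitive_only"
    COOPERATIVE_ONLY = "cooperative_only"


class HubCategory(str, Enum):
    COMPETITIVE = "competitive"
    MODEST = "modest"
    COOPERATIVE = "cooperative"


@dataclass(frozen=True)
class DegreeDistribution:
    degrees: dict[str, int]
    pk: dict[int, float]  # degree k -> fraction of nodes with degree k


@dataclass(frozen=True)
class PowerLawFit:
    coefficient: float  # prefactor a in P(k) = a * k^(-exponent)
    exponent: float
    r_squared: float


@dataclass(frozen=True)
class HubRecord:
    protein: str
    degree: int
    competitive_fraction: float
    category: HubCategory
    clustering_coefficient: float
    participation_coefficient: float | None = None


@dataclass
class ModulePartition:
    """Disjoint node modules; small ones flagged as not retained."""

    modules: list[frozenset[str]]
    retained: list[bool]
    source_edges: str = "all"

    def module_of(self, node: str) -> int:
        for idx, members in enumerate(self.modules):
            if node in members:
                return idx
        raise KeyError(node)

    def node_to_module(self) -> dict[str, int]:
        return {n: i for i, members in enumerate(self.modules) for n in members}

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def retained_nodes(self) -> set[str]:
        return {
            n
            for members, keep in zip(self.modules, self.retained)
            if keep
            for n in members
        }


# ---------------------------------------------------------------------------
# Degree distribution and power-law fit
# ---------------------------------------------------------------------------

def degree_distribution(net: CCRN | nx.Graph) -> DegreeDistribution:
    graph = net.graph if isinstance(net, CCRN) else net
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = {n: d for n, d in graph.degree()}
    n = len(degrees)
    pk: dict[int, float] = {}
    for d in degrees.values():
        pk[d] = pk.get(d, 0.0) + 1.0 / n
    return DegreeDistribution(degrees=degrees, pk=dict(sorted(pk.items())))


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Least-squares line on (log k, log P(k)) over degrees with P(k) > 0."""
    points = [(k, p) for k, p in dist.pk.items() if p > 0 and k > 0]
    if len(points) < 3:
        raise ValueError("power-law fit needs at least 3 distinct degrees")
    log_k = np.log([k for k, _ in points])
    log_p = np.log([p for _, p in points])
    slope, intercept = np.polyfit(log_k, log_p, 1)
    predicted = slope * log_k + intercept
    ss_res = float(np.sum((log_p - predicted) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(coefficient=float(np.exp(intercept)), exponent=float(-slope), r_squared=r2)


# ---------------------------------------------------------------------------
# Hub classification
# ---------------------------------------------------------------------------

def hub_degree_cutoff(net: CCRN, top_fraction: float = 0.2) -> int:
    """Degree of the node at rank ceil(top_fraction * N), sorted descending."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    degrees = sorted((d for _, d in net.graph.degree()), reverse=True)
    if not degrees:
        raise ValueError("empty network")
    rank = math.ceil(top_fraction * len(degrees))
    return degrees[rank - 1]


def categorize(competitive_fraction: float) -> HubCategory:
    if competitive_fraction > 2 / 3:
        return HubCategory.COMPETITIVE
    if competitive_fraction < 1 / 3:
        return HubCategory.COOPERATIVE
    return HubCategory.MODEST


def classify_hubs(net: CCRN, top_fraction: float = 0.2) -> list[HubRecord]:
    """All hubs (top-fraction degrees, ties included) with their categories."""
    cutoff = hub_degree_cutoff(net, top_fraction)
    records = []
    for node, degree in net.graph.degree():
        if degree < cutoff:
            continue
        comp = sum(
            1
            for _, _, data in net.graph.edges(node, data=True)
            if data["relation"] == Relation.COMPETITIVE.value
        )
        frac = comp / degree
        records.append(
            HubRecord(
                protein=node,
                degree=degree,
                competitive_fraction=frac,
                category=categorize(frac),
                clustering_coefficient=clustering_coefficient(net, node),
            )
        )
    return sorted(records, key=lambda r: (-r.degree, r.protein))


def clustering_coefficient(
    net: CCRN, node: str, edge_filter: EdgeFilter = EdgeFilter.ALL
) -> float:
    """c_i = 2 e_i / (k_i (k_i - 1)) with neighbours/edges passing the filter."""
    edge_filter = EdgeFilter(edge_filter)
    if node not in net.graph:
        raise KeyError(node)
    if edge_filter is EdgeFilter.ALL:
        graph = net.graph
    elif edge_filter is EdgeFilter.COMPETITIVE_ONLY:
        graph = net.subgraph_by_relation(Relation.COMPETITIVE)
    else:
        graph = net.subgraph_by_relation(Relation.COOPERATIVE)
    if node not in graph:
        return 0.0
    neighbors = set(graph.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = sum(
        1
        for u, v in graph.subgraph(neighbors).edges()
        if u != node and v != node
    )
    return 2.0 * e / (k * (k - 1))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_component(
    nodes: list[str],
    graph: nx.Graph,
    inflation: float,
    max_iter: int,
    prune_threshold: float,
    convergence_tol: float,
) -> list[list[str]]:
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v in graph.subgraph(nodes).edges():
        m[index[u], index[v]] = 1.0
        m[index[v], index[u]] = 1.0
    np.fill_diagonal(m, 1.0)  # self-loops, weight 1
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < prune_threshold] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        change = float(np.abs(inflated - m).max())
        m = inflated
        if change < convergence_tol:
            break

    # Attractor rows (non-zero diagonal) span the clusters; overlapping nodes
    # go to the attractor giving them the most mass, ties to the lowest index.
    attractors = [i for i in range(n) if m[i, i] > prune_threshold]
    if not attractors:
        return [list(nodes)]
    # Merge attractors that support each other (one attractor system = one cluster)
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai, a in enumerate(attractors):
        for bi, b in enumerate(attractors):
            if bi <= ai:
                continue
            if m[a, b] > 0 or m[b, a] > 0:
                ra, rb = find(ai), find(bi)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    roots = sorted({find(i) for i in range(len(attractors))})
    root_order = {r: k for k, r in enumerate(roots)}
    clusters: list[list[str]] = [[] for _ in roots]
    for j in range(n):
        masses = [(m[a, j], -ai) for ai, a in enumerate(attractors)]
        best_ai = -max(masses)[1]
        clusters[root_order[find(best_ai)]].append(nodes[j])
    return [c for c in clusters if c]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    prune_threshold: float = 1e-6,
    convergence_tol: float = 1e-8,
    min_module_size: int = 4,
    source_edges: str = "all",
) -> ModulePartition:
    """Markov Cluster algorithm, run independently on each connected component.

    Alternates expansion (matrix squaring) and inflation (elementwise power
    ``inflation`` with column renormalisation) on the column-stochastic
    transition matrix with unit self-loops, pruning entries below
    ``prune_threshold``, until the matrix changes by less than
    ``convergence_tol`` or ``max_iter`` iterations.  Modules with at most
    ``min_module_size`` nodes are flagged as not retained.
    """
    if inflation <= 0:
        raise ValueError("inflation must be positive")
    modules: list[frozenset[str]] = []
    for component in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        nodes = sorted(component)
        for cluster in _mcl_component(
            nodes, graph, inflation, max_iter, prune_threshold, convergence_tol
        ):
            modules.append(frozenset(cluster))
    modules.sort(key=lambda s: (-len(s), sorted(s)[0]))
    retained = [len(s) > min_module_size for s in modules]
    return ModulePartition(modules=modules, retained=retained, source_edges=source_edges)


def participation_coefficient(
    graph: nx.Graph, partition: ModulePartition, node: str
) -> float | None:
    """p_i = 1 - sum_s (k_is / k_i)^2 over retained modules.

    Neighbours in removed (non-retained) modules are excluded from both k_i
    and k_is.  Returns ``None`` (undefined) when the node's own module is not
    retained or it has no neighbours in retained modules.
    """
    if node not in graph:
        raise KeyError(node)
    node_to_module = partition.node_to_module()
    if node not in node_to_module:
        raise KeyError(f"{node!r} absent from the module partition")
    if not partition.retained[node_to_module[node]]:
        return None
    retained = partition.retained_nodes()
    per_module: dict[int, int] = {}
    k = 0
    for neighbor in graph.neighbors(node):
        if neighbor not in retained:
            continue
        k += 1
        s = node_to_module[neighbor]
        per_module[s] = per_module.get(s, 0) + 1
    if k == 0:
        return None
    return 1.0 - sum((ks / k) ** 2 for ks in per_module.values())


def hub_associated_modules(
    competitive_subgraph: nx.Graph,
    hubs: Sequence[HubRecord],
    inflation: float = 2.0,
    min_module_size: int = 4,
) -> tuple[ModulePartition, dict[tuple[str, str], str | None]]:
    """Cluster the competitive subgraph; label competitive pairs by position.

    Hub-associated modules contain at least one competitive hub.  A pair is
    *intra* when both endpoints sit in the same hub-associated module, *inter*
    when exactly one endpoint is in a hub-associated module and the other in a
    different module; other pairs are left unlabelled (``None``).
    """
    competitive_hubs = {h.protein for h in hubs if h.category is HubCategory.COMPETITIVE}
    if not competitive_hubs:
        raise ValueError("no competitive hubs: hub-associated modules are undefined")
    partition = mcl_cluster(
        competitive_subgraph,
        inflation=inflation,
        min_module_size=min_module_size,
        source_edges="competitive_only",
    )
    node_to_module = partition.node_to_module()
    associated = {
        idx
        for idx, members in enumerate(partition.modules)
        if members & competitive_hubs
    }
    labels: dict[tuple[str, str], str | None] = {}
    for u, v in competitive_subgraph.edges():
        pair = tuple(sorted((u, v)))
        mu, mv = node_to_module[u], node_to_module[v]
        if mu == mv and mu in associated:
            labels[pair] = "intra"
        elif mu != mv and (mu in associated or mv in associated):
            labels[pair] = "inter"
        else:
            labels[pair] = None
    return partition, labels
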