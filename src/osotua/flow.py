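"""Analysis of disaster-activated gift-flow networks.

The support network defines where cattle *could* flow; the gift log of a
run defines where it *did*.  Collapsing all gift events of a run into one
directed edge per (giver, receiver) pair yields the activated flow network,
a dual picture of the social structure that the disasters actually evoked.
Its sparseness, clustering and cycle content discriminate sharply between
disaster-correlation regimes, so this module computes those metrics along
with degree-preserving randomized baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .dynamics import GiftEvent
from .network import degree_preserving_shuffle

__all__ = [
    "FlowNetwork",
    "FlowMetrics",
    "CycleCount",
    "build_flow_network",
    "average_path_length",
    "average_degree",
    "clustering_coefficient",
    "count_cycles",
    "metrics_to_csv",
    "null_model_metrics",
]


@dataclass
class FlowNetwork:
    """Directed activated network: one edge per (giver, receiver) pair.

    ``edges`` maps the ordered pair to its weight, the number of gift events
    that flowed along it over the whole run.  ``alive`` flags node status at
    the horizon (activated edges of since-eliminated nodes are retained).
    """

    n: int
    edges: dict[tuple[int, int], int]
    alive: np.ndarray | None = None

    def non_isolated(self) -> list[int]:
        touched = set()
        for u, v in self.edges:
            touched.add(u)
            touched.add(v)
        return sorted(touched)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    def undirected_projection(self) -> nx.Graph:
        """Undirected simple graph on the non-isolated nodes only."""
        g = nx.Graph()
        g.add_nodes_from(self.non_isolated())
        g.add_edges_from((u, v) for u, v in self.edges)
        return g

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("giver,receiver,weight\n")
            for (u, v), w in sorted(self.edges.items()):
                fh.write(f"{u},{v},{w}\n")


class CycleCount(NamedTuple):
    count: int
    capped: bool


@dataclass
class FlowMetrics:
    """Per-network flow metrics with degree-preserving null baselines."""

    avg_path_length: float
    avg_degree: float
    clustering: float
    n_cycles: float
    null_clustering: float | None = None
    null_cycles: float | None = None


def metrics_to_csv(rows: Sequence[tuple], path) -> None:
    """Write per-cell flow metrics as `scenario,beta,metric,observed,null_mean`."""
    with open(path, "w") as fh:
        fh.write("scenario,beta,metric,observed,null_mean\n")
        for scenario, beta, metric, observed, null_mean in rows:
            null = "" if null_mean is None else f"{null_mean:.6g}"
            fh.write(f"{scenario},{beta},{metric},{observed:.6g},{null}\n")


def build_flow_network(
    gifts: Iterable[GiftEvent], n: int, alive: np.ndarray | None = None
) -> FlowNetwork:
    edges: dict[tuple[int, int], int] = {}
    for g in gifts:
        if not (0 <= g.giver < n and 0 <= g.receiver < n):
            raise ValueError(f"gift references node outside 0..{n - 1}: {g}")
        key = (g.giver, g.receiver)
        edges[key] = edges.get(key, 0) + 1
    return FlowNetwork(n=n, edges=edges, alive=alive)


def average_path_length(flow: FlowNetwork) -> float:
    """Mean shortest-path length over connected ordered pairs of active nodes.

    Distances are measured on the undirected projection; isolated nodes are
    excluded, and pairs in different components do not contribute.  An
    edgeless network has path length 0 by convention.
    """
    g = flow.undirected_projection()
    total = 0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    return total / pairs if pairs else 0.0


def average_degree(flow: FlowNetwork) -> float:
    """Mean total (in + out) degree over non-isolated nodes; 0 if edgeless."""
    active = flow.non_isolated()
    if not active:
        return 0.0
    return 2.0 * len(flow.edges) / len(active)


def clustering_coefficient(flow: FlowNetwork) -> float:
    """Mean local clustering of the undirected projection over active nodes."""
    g = flow.undirected_projection()
    if g.number_of_nodes() == 0:
        return 0.0
    return nx.average_clustering(g)


def _cyclomatic_number(g: nx.Graph) -> int:
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def count_cycles(
    flow: FlowNetwork | nx.DiGraph,
    method: str = "simple_directed",
    cap: int = 100_000,
) -> CycleCount:
    """Count cycles in the flow network.

    ``simple_directed`` enumerates elementary directed circuits (including
    reciprocal two-cycles), aborting at ``cap`` circuits; ``cyclomatic``
    returns |E| - |V| + #components of the undirected projection restricted
    to non-isolated nodes.
    """
    if method == "cyclomatic":
        g = (
            flow.undirected_projection()
            if isinstance(flow, FlowNetwork)
            else nx.Graph(flow.subgraph([v for v in flow if flow.degree(v) > 0]))
        )
        return CycleCount(_cyclomatic_number(g), False)
    if method != "simple_directed":
        raise ValueError(f"unknown cycle-count method {method!r}")
    dg = flow.to_digraph() if isinstance(flow, FlowNetwork) else flow
    count = 0
    for _ in nx.simple_cycles(dg):
        count += 1
        if count >= cap:
            return CycleCount(count, True)
    return CycleCount(count, False)


def null_model_metrics(
    flow: FlowNetwork,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    cycle_method: str = "simple_directed",
    swaps_per_edge: int = 10,
    cycle_cap: int = 100_000,
) -> FlowMetrics:
    """Observed metrics plus degree-preserving randomized baselines.

    Each of ``reps`` randomizations rewires the directed edge set by double
    edge swaps (in- and out-degree sequences conserved exactly) and records
    clustering and cycle count; the null values are ensemble means.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    observed = FlowMetrics(
        avg_path_length=average_path_length(flow),
        avg_degree=average_degree(flow),
        clustering=clustering_coefficient(flow),
        n_cycles=count_cycles(flow, method=cycle_method, cap=cycle_cap).count,
    )
    if not flow.edges:
        observed.null_clustering = 0.0
        observed.null_cycles = 0.0
        return observed
    clust = np.empty(reps)
    cycles = np.empty(reps)
    n_swaps = max(swaps_per_edge * len(flow.edges), 1)
    for r in range(reps):
        shuffled = degree_preserving_shuffle(
            flow.edges.keys(), n_swaps, rng, directed=True
        )
        null = FlowNetwork(n=flow.n, edges={e: 1 for e in shuffled})
        clust[r] = clustering_coefficient(null)
        cycles[r] = count_cycles(null, method=cycle_method, cap=cycle_cap).count
    observed.null_clustering = float(clust.mean())
    observed.null_cycles = float(cycles.mean())
    return observed
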