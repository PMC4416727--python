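"""Spatially embedded support networks.

The support (potential-transfer) network starts as a ring lattice whose node
index doubles as a physical position: disasters are located in space, and a
node's exposure is determined by its pre-rewiring ring position, not by who
it is linked to.  Rewiring a fraction ``beta`` of the edges then introduces
spatial heterogeneity — long-range support links that may reach outside a
disaster's correlation length — while keeping the mean degree fixed.

A configuration-model power-law alternative and a degree-preserving
double-edge-swap randomizer (used for flow-network null models) live here
too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SpatialNetwork",
    "ring_lattice",
    "rewire",
    "powerlaw_network",
    "degree_preserving_shuffle",
]


def _norm_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass
class SpatialNetwork:
    """Undirected support network with a fixed spatial embedding.

    ``spatial_index[i]`` is node i's position on the physical ring (a
    permutation of ``0..n-1``); for ring-rewired networks it is the identity,
    since the pre-rewiring index *is* the position.
    """

    n: int
    edges: set[tuple[int, int]]
    spatial_index: np.ndarray
    beta: float = 0.0
    k: int | None = None
    generator: str = "ring"

    def __post_init__(self) -> None:
        self.spatial_index = np.asarray(self.spatial_index, dtype=int)
        if sorted(self.spatial_index.tolist()) != list(range(self.n)):
            raise ValueError("spatial_index must be a permutation of 0..n-1")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u}, {v}) references a missing node")
            if u > v:
                raise ValueError("edges must be stored as (u, v) with u < v")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def mean_degree(self) -> float:
        return 2.0 * len(self.edges) / self.n

    def neighbor_lists(self) -> list[np.ndarray]:
        """Adjacency as one sorted integer array per node."""
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [np.array(sorted(a), dtype=int) for a in adj]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def to_csv(self, out_dir: str | Path, prefix: str = "network") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{prefix}_edges.csv", "w") as fh:
            fh.write("u,v\n")
            for u, v in sorted(self.edges):
                fh.write(f"{u},{v}\n")
        meta = {
            "n": self.n,
            "beta": self.beta,
            "k": self.k,
            "generator": self.generator,
        }
        with open(out / f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def ring_lattice(n: int, k: int) -> SpatialNetwork:
    """Homogeneous ring: every node linked to its k/2 nearest neighbors per side."""
    if k % 2 != 0:
        raise ValueError("k must be even")
    if n <= k:
        raise ValueError("need n > k")
    edges = set()
    for i in range(n):
        for j in range(1, k // 2 + 1):
            edges.add(_norm_edge(i, (i + j) % n))
    return SpatialNetwork(
        n=n, edges=edges, spatial_index=np.arange(n), beta=0.0, k=k, generator="ring"
    )


def rewire(net: SpatialNetwork, beta: float, rng: np.random.Generator) -> SpatialNetwork:
    """Watts-Strogatz-style rewiring of a fraction ``beta`` of the edges.

    Each edge is independently selected with probability ``beta``; a selected
    edge keeps one (randomly chosen) endpoint and the other is reattached to
    a uniformly drawn node, rejecting self-loops and duplicate edges.  Edge
    count — hence mean degree — is conserved exactly.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    edges = set(net.edges)
    if beta > 0.0:
        original = sorted(net.edges)
        selected = rng.random(len(original)) < beta
        for (u, v), sel in zip(original, selected):
            if not sel:
                continue
            keep = u if rng.integers(2) == 0 else v
            edges.discard((u, v))
            placed = False
            for _ in range(200):
                w = int(rng.integers(net.n))
                if w == keep:
                    continue
                cand = _norm_edge(keep, w)
                if cand in edges:
                    continue
                edges.add(cand)
                placed = True
                break
            if not placed:  # saturated neighborhood; keep the original edge
                edges.add((u, v))
    return SpatialNetwork(
        n=net.n,
        edges=edges,
        spatial_index=net.spatial_index.copy(),
        beta=beta,
        k=net.k,
        generator=net.generator,
    )


def _powerlaw_degrees(
    n: int, mean_degree: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer degree sequence from a truncated Pareto scaled to the mean.

    Continuous Pareto draws ``k_min * u**(-1/(exponent-1))`` have mean
    ``k_min * (exponent-1) / (exponent-2)``; rounding and truncation at n-1
    shift the mean, so k_min is rescaled once from a pilot estimate.
    """
    if exponent <= 2.0:
        raise ValueError("exponent must exceed 2 for a finite mean")
    k_min = mean_degree * (exponent - 2.0) / (exponent - 1.0)
    for _ in range(8):
        u = rng.random(n)
        deg = np.rint(k_min * u ** (-1.0 / (exponent - 1.0))).astype(int)
        deg = np.clip(deg, 1, n - 1)
        realized = deg.mean()
        if abs(realized - mean_degree) <= 0.05 * mean_degree:
            return deg
        k_min *= mean_degree / realized
    return deg


def powerlaw_network(
    n: int,
    mean_degree: float,
    rng: np.random.Generator,
    exponent: float = 2.5,
    max_tries: int = 50,
) -> SpatialNetwork:
    """Connected simple graph with a power-law degree sequence.

    Built with the configuration model, then simplified (self-loops and
    parallel edges dropped) and stitched into one component; the realized
    mean degree is required to land within 10% of the target.  Ring positions
    are assigned by a uniform random permutation, since a power-law graph has
    no intrinsic spatial order.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    for _ in range(max_tries):
        deg = _powerlaw_degrees(n, mean_degree, exponent, rng)
        if deg.sum() % 2 == 1:
            deg[int(rng.integers(n))] += 1
        g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        giant = list(comps[0])
        for comp in comps[1:]:
            a = int(rng.choice(np.array(list(comp))))
            b = int(rng.choice(np.array(giant)))
            g.add_edge(a, b)
        realized = 2.0 * g.number_of_edges() / n
        if abs(realized - mean_degree) <= 0.10 * mean_degree:
            edges = {_norm_edge(u, v) for u, v in g.edges()}
            return SpatialNetwork(
                n=n,
                edges=edges,
                spatial_index=rng.permutation(n),
                beta=0.0,
                k=None,
                generator="powerlaw",
            )
    raise RuntimeError("could not realize a power-law degree sequence at the target mean")


def degree_preserving_shuffle(
    edges: Iterable[tuple[int, int]],
    n_swaps: int,
    rng: np.random.Generator,
    directed: bool = False,
) -> set[tuple[int, int]]:
    """Randomize an edge set by repeated double-edge swaps.

    Two edges (a, b), (c, d) become (a, d), (c, b); for undirected input the
    pairing orientation is chosen at random.  Swaps creating self-loops or
    duplicate edges are rejected, so the (in/out) degree sequence is
    conserved exactly.  Returns the shuffled edge set; a warning is emitted
    when fewer than half of the attempted swaps were feasible.
    """
    edge_list = list(edges)
    if not directed:
        edge_list = [_norm_edge(u, v) for u, v in edge_list]
    if len(edge_list) < 2:
        return set(edge_list)
    eset = set(edge_list)
    if len(eset) != len(edge_list):
        raise ValueError("duplicate edges in input")
    applied = 0
    for _ in range(n_swaps):
        i, j = rng.integers(len(edge_list), size=2)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if directed:
            new1, new2 = (a, d), (c, b)
        else:
            if rng.integers(2) == 0:
                new1, new2 = _norm_edge(a, d), _norm_edge(c, b)
            else:
                new1, new2 = _norm_edge(a, c), _norm_edge(b, d)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        if new1 == new2 or new1 in eset or new2 in eset:
            continue
        eset.discard(edge_list[i])
        eset.discard(edge_list[j])
        eset.add(new1)
        eset.add(new2)
        edge_list[i], edge_list[j] = new1, new2
        applied += 1
    if applied < min(n_swaps, len(edge_list)):  # under-mixed: flag it
        warnings.warn(
            f"only {applied}/{n_swaps} double-edge swaps were feasible",
            RuntimeWarning,
            stacklevel=2,
        )
    return eset
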