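"""Graph-theoretic validation of snapshots: small-world analysis.

Snapshots are binarized by proportional thresholding (keep the strongest
``density`` fraction of off-diagonal |weights|), then characterized by the
global clustering coefficient C (transitivity: three times the number of
closed triples over all connected triples) and the characteristic path
length L (mean shortest-path length over connected pairs).  Both are
referenced against degree-preserving rewired null graphs:

    gamma = C / C_R,   lambda = L / L_R,   sigma = gamma / lambda,

with sigma > 1 the standard signature of small-world organization, the
property healthy functional brain networks are expected to retain in most
snapshots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .snapshots import Snapshot, SnapshotSequence

logger = logging.getLogger("dynbrain")

__all__ = [
    "BinaryGraph",
    "SmallWorldRecord",
    "binarize",
    "global_clustering",
    "char_path_length",
    "random_reference",
    "small_world",
    "small_world_fraction",
    "records_to_frame",
]


@dataclass(frozen=True)
class BinaryGraph:
    """Simple undirected graph: node count and a frozenset of (i, j) pairs, i<j."""

    n_nodes: int
    edges: frozenset

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) outside [0, {self.n_nodes})")
            if i > j:
                raise ValueError("edges must be stored as (i, j) with i < j")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BinaryGraph":
        edges = frozenset((min(u, v), max(u, v)) for u, v in g.edges())
        return cls(n_nodes=g.number_of_nodes(), edges=edges)

    @property
    def degree_sequence(self) -> tuple:
        deg = [0] * self.n_nodes
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return tuple(sorted(deg))


@dataclass
class SmallWorldRecord:
    """Per-snapshot small-world summary: C, L, null means C_R/L_R and the
    ratios gamma=C/C_R, lambda=L/L_R, sigma=gamma/lambda."""

    C: float
    L: float
    C_R: float
    L_R: float
    gamma: float
    lam: float
    sigma: float
    is_small_world: bool
    disconnected: bool = False
    undefined: bool = False


def binarize(snapshot: Snapshot | np.ndarray, density: float) -> BinaryGraph:
    """Proportional threshold: keep the top ``density`` fraction of
    off-diagonal |weights| as edges; cutoff ties broken by (i, j) order."""
    mat = snapshot.matrix if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    m = mat.shape[0]
    if mat.shape != (m, m):
        raise ValueError("snapshot matrix must be square")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    iu = np.triu_indices(m, k=1)
    w = np.abs(mat[iu])
    k = int(round(density * w.size))
    if k < 1:
        raise ValueError(f"density {density} keeps no edges for m={m}")
    order = np.lexsort((iu[1], iu[0], -w))
    keep = order[:k]
    edges = frozenset((int(iu[0][e]), int(iu[1][e])) for e in keep)
    return BinaryGraph(n_nodes=m, edges=edges)


def global_clustering(g: BinaryGraph) -> float:
    """Transitivity: 3 x triangles / connected triples (0 if no triples)."""
    if g.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    return float(nx.transitivity(g.to_networkx()))


def char_path_length(g: BinaryGraph) -> tuple[float, bool]:
    """Mean shortest-path length over connected pairs.

    Disconnected graphs are evaluated on the largest connected component
    (warned, flagged in the second return value).  Edgeless graphs raise.
    """
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not g.edges:
        raise ValueError("edgeless graph has no path length")
    G = g.to_networkx()
    disconnected = not nx.is_connected(G)
    if disconnected:
        comp = max(nx.connected_components(G), key=len)
        G = G.subgraph(comp)
        logger.warning(
            "disconnected graph: path length on largest component (%d/%d nodes)",
            len(comp), g.n_nodes,
        )
    return float(nx.average_shortest_path_length(G)), disconnected


def random_reference(g: BinaryGraph, n_swaps_per_edge: int = 10, seed: int = 0) -> BinaryGraph:
    """Degree-preserving null model via double-edge swaps.

    Returns a rewired graph with exactly g's degree sequence; graphs that
    admit no valid swap (e.g. stars) are returned unchanged with a warning.
    """
    if len(g.edges) < 2:
        raise ValueError("need at least 2 edges to rewire")
    G = g.to_networkx()
    n_edges = G.number_of_edges()
    try:
        nx.double_edge_swap(
            G,
            nswap=n_swaps_per_edge * n_edges,
            max_tries=100 * n_swaps_per_edge * n_edges,
            seed=seed,
        )
    except nx.NetworkXError:
        logger.warning("no valid double-edge swap exists; returning graph unchanged")
        return g
    except nx.NetworkXAlgorithmError:
        logger.warning("swap budget exhausted before requested swap count")
    out = BinaryGraph.from_networkx(G)
    assert out.degree_sequence == g.degree_sequence, "degree sequence not preserved"
    return out


def small_world(g: BinaryGraph, n_random: int = 20, seed: int = 0) -> SmallWorldRecord:
    """C, L against means over ``n_random`` rewired references; sigma = gamma/lambda."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    C = global_clustering(g)
    L, disconnected = char_path_length(g)
    Cs, Ls = [], []
    for r in range(n_random):
        ref = random_reference(g, seed=seed + r)
        Cs.append(global_clustering(ref))
        Ls.append(char_path_length(ref)[0])
    C_R = float(np.mean(Cs))
    L_R = float(np.mean(Ls))
    if C_R == 0.0 or L_R == 0.0:
        return SmallWorldRecord(C, L, C_R, L_R, math.nan, math.nan, math.nan,
                                False, disconnected, undefined=True)
    gamma = C / C_R
    lam = L / L_R
    sigma = gamma / lam
    return SmallWorldRecord(C, L, C_R, L_R, gamma, lam, sigma,
                            bool(sigma > 1.0), disconnected)


def small_world_fraction(
    snapshots: SnapshotSequence,
    density: float = 0.15,
    n_random: int = 20,
    seed: int = 0,
) -> tuple[float, int, int, list[SmallWorldRecord]]:
    """Fraction of snapshots with sigma > 1, plus raw counts and records.

    Each snapshot's null ensemble is seeded from the master seed plus the
    snapshot index, so the whole evaluation is reproducible.
    """
    if len(snapshots) == 0:
        raise ValueError("empty snapshot sequence")
    records = []
    for k, snap in enumerate(snapshots):
        rec = small_world(binarize(snap, density), n_random=n_random,
                          seed=seed + 1000 * k)
        records.append(rec)
    count = sum(1 for r in records if r.is_small_world)
    total = len(records)
    frac = count / total
    logger.info("small-world fraction: %.1f%%(%d/%d)", 100 * frac, count, total)
    return frac, count, total, records


def records_to_frame(records: list[SmallWorldRecord],
                     times: np.ndarray | None = None) -> pd.DataFrame:
    """One row per snapshot with columns C, L, C_R, L_R, gamma, lambda, sigma,
    is_small_world (CSV-ready)."""
    df = pd.DataFrame(
        {
            "C": [r.C for r in records],
            "L": [r.L for r in records],
            "C_R": [r.C_R for r in records],
            "L_R": [r.L_R for r in records],
            "gamma": [r.gamma for r in records],
            "lambda": [r.lam for r in records],
            "sigma": [r.sigma for r in records],
            "is_small_world": [r.is_small_world for r in records],
        }
    )
    if times is not None:
        df.insert(0, "time_index", np.asarray(times, dtype=float))
    return df
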