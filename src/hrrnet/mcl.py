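"""Markov Cluster Algorithm (MCL) with deterministic cluster extraction.

MCL simulates flow on the graph: the column-stochastic transition matrix
is alternately *expanded* (raised to a matrix power, letting flow spread)
and *inflated* (raised to an entrywise power and renormalised, sharpening
strong flow and starving weak flow).  The process converges to a
doubly-idempotent matrix whose attractor structure defines the clusters.
The inflation parameter I controls granularity: larger I yields more,
smaller clusters.

This implementation is dense (NumPy), which is the right trade-off for
co-expression networks of a few hundred to a few thousand genes, and is
fully deterministic: ties in attractor assignment are resolved by cluster
size then cluster id, and cluster ids themselves are assigned by size
(descending) then lexicographically smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = ["MCLParams", "ClusterSet", "mcl", "drop_meaningless", "write_clusters_tsv", "read_clusters_tsv"]


@dataclass(frozen=True)
class MCLParams:
    """Tunable knobs of the Markov Cluster Algorithm.

    inflation
        Entrywise power I > 1 applied after each expansion; 3.0 gives a
        fine-grained clustering suitable for tight co-expression cliques.
    expansion
        Matrix power e >= 2 (2 is the canonical random-walk step).
    isolated_loop_weight
        Each node receives a self-loop equal to its strongest incident
        edge weight before normalisation (canonical MCL), keeping the
        loop on the scale of the node's own flow; nodes with no edges
        get this constant instead so their column stays defined.
    prune_threshold
        Entries below this are zeroed after inflation (with the column
        maximum always retained), keeping the iteration sparse in effect.
    """

    inflation: float = 3.0
    expansion: int = 2
    isolated_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    max_iter: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ClusterSet:
    """Disjoint clusters over the graph's nodes.

    Clusters are tuples of node ids sorted lexicographically; cluster ids
    are 1-based, ordered by size (descending) then by smallest member.
    """

    clusters: tuple
    unassigned: tuple = ()
    iterations_used: int = 0
    converged: bool = True

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def assignment(self) -> dict:
        out: dict = {}
        for cid, members in enumerate(self.clusters, start=1):
            for gene in members:
                out[gene] = cid
        return out

    def as_sets(self) -> list[frozenset]:
        return [frozenset(c) for c in self.clusters]


def _order_clusters(groups: Iterable[Iterable[str]]) -> tuple:
    normed = [tuple(sorted(g)) for g in groups if len(tuple(g))]
    normed.sort(key=lambda c: (-len(c), c[0]))
    return tuple(normed)


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0, keepdims=True)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl(g: nx.Graph, params: MCLParams = MCLParams()) -> ClusterSet:
    """Cluster an undirected weighted graph by Markov flow simulation.

    Edge weights are taken from the ``weight`` attribute (default 1.0)
    and must be positive.  Flow can never cross connected components, so
    clusters always refine the component structure.  On non-convergence
    within ``max_iter`` the current clustering is returned with
    ``converged=False``.
    """
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n), dtype=float)
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u}, {v})")
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    # self-loops: strongest incident weight (isolated nodes get a constant)
    incident_max = a.max(axis=0)
    incident_max[incident_max == 0] = params.isolated_loop_weight
    np.fill_diagonal(a, incident_max)

    m = _column_normalize(a)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        nxt = np.linalg.matrix_power(m, params.expansion)
        np.power(nxt, params.inflation, out=nxt)
        nxt = _column_normalize(nxt)
        # prune weak flow but never empty a column
        col_max = nxt.max(axis=0, keepdims=True)
        nxt[(nxt < params.prune_threshold) & (nxt < col_max)] = 0.0
        nxt = _column_normalize(nxt)
        delta = np.abs(nxt - m).max()
        m = nxt
        if delta < params.convergence_tol:
            converged = True
            break

    clusters, unassigned = _extract_clusters(m, nodes)
    return ClusterSet(
        clusters=_order_clusters(clusters),
        unassigned=tuple(sorted(unassigned)),
        iterations_used=iterations,
        converged=converged,
    )


def _extract_clusters(m: np.ndarray, nodes: Sequence[str]):
    """Interpret the limit matrix: attractors seed clusters, others follow flow.

    Attractors are rows with positive diagonal (positive return flow).
    Attractors linked by residual flow form one attractor system; every
    non-attractor node joins the system receiving most of its outgoing
    flow, ties resolved toward the larger then lower-id cluster.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:  # pathological; treat every node as unassigned
        return [], list(nodes)
    # union attractors sharing any flow (symmetrised adjacency restricted to attractors)
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > 0 or m[j, i] > 0):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: (-len(s), s[0]))
    member_sets: list[set] = [set(s) for s in systems]
    unassigned: list[str] = []
    attractor_set = set(attractors)
    for v in range(n):
        if v in attractor_set:
            continue
        flows = np.array([m[list(s), v].sum() for s in systems])
        if flows.max() <= 0:
            unassigned.append(nodes[v])
            continue
        # max flow; ties -> larger system, then earlier (lower) system id
        best = int(
            min(
                range(len(systems)),
                key=lambda k: (-flows[k], -len(systems[k]), k),
            )
        )
        member_sets[best].add(v)
    clusters = [[nodes[i] for i in s] for s in member_sets]
    return clusters, unassigned


def drop_meaningless(
    cs: ClusterSet,
    verdicts: Mapping[int, bool],
    min_size: int = 3,
    rule: str = "or",
) -> ClusterSet:
    """Remove clusters judged biologically meaningless.

    With ``rule="or"`` (default) a cluster is removed if it is smaller
    than ``min_size`` OR has no significantly enriched term — i.e. a
    surviving cluster must be both large enough and annotated.  With
    ``rule="and"`` removal requires both defects at once.  ``verdicts``
    maps cluster id -> whether any significant term exists.  Removed
    genes move to ``unassigned`` and ids are recomputed.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    kept: list[tuple] = []
    dropped: list[str] = list(cs.unassigned)
    for cid, members in enumerate(cs.clusters, start=1):
        small = len(members) < min_size
        unannotated = not verdicts.get(cid, False)
        remove = (small or unannotated) if rule == "or" else (small and unannotated)
        if remove:
            dropped.extend(members)
        else:
            kept.append(members)
    return ClusterSet(
        clusters=_order_clusters(kept),
        unassigned=tuple(sorted(dropped)),
        iterations_used=cs.iterations_used,
        converged=cs.converged,
    )


def write_clusters_tsv(cs: ClusterSet, path) -> None:
    """Write gene -> cluster assignment (unassigned genes get cluster_id 0)."""
    with open(path, "w") as handle:
        handle.write("gene\tcluster_id\n")
        for cid, members in enumerate(cs.clusters, start=1):
            for gene in members:
                handle.write(f"{gene}\t{cid}\n")
        for gene in cs.unassigned:
            handle.write(f"{gene}\t0\n")


def read_clusters_tsv(path) -> ClusterSet:
    """Read an external clustering in the same TSV layout (e.g. clusterMaker export)."""
    groups: dict[int, list] = {}
    unassigned: list = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "cluster_id"]:
            raise ValueError(f"{path}: expected header 'gene<TAB>cluster_id'")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                gene, cid = line.split("\t")
                cid = int(cid)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row") from exc
            if cid == 0:
                unassigned.append(gene)
            else:
                groups.setdefault(cid, []).append(gene)
    return ClusterSet(
        clusters=_order_clusters(groups.values()),
        unassigned=tuple(sorted(unassigned)),
    )
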