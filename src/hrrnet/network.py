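"""Pearson correlation, highest-reciprocal-rank transform and network build.

The co-expression graph is built in three steps: (1) an all-pairs Pearson
correlation matrix over replicate-level samples; (2) the highest reciprocal
rank (HRR) transform — for each gene, partners are ranked by descending
|r| (rank 1 = strongest) and HRR(A, B) is the larger of B's rank in A's
list and A's rank in B's; (3) an edge is kept when |r| clears the
correlation threshold and HRR clears the rank cutoff.  Low HRR therefore
means two genes are mutually among each other's top co-expression
partners, which is robust to the overall correlation level of a gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix, stage_means

__all__ = [
    "CorrelationMatrix",
    "TopologyReport",
    "pearson_matrix",
    "hrr_transform",
    "build_network",
    "topology_report",
    "write_sif",
    "write_graphml",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix over a gene set.

    ``constant_genes`` flags zero-variance genes whose correlations are
    undefined; their off-diagonal entries are stored as 0 and they are
    excluded from network construction.
    """

    gene_ids: tuple
    r: np.ndarray
    constant_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match gene ids")

    def index_of(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def value(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])


def pearson_matrix(
    matrix: ExpressionMatrix,
    genes: Iterable[str] | None = None,
    stage_level: bool = False,
) -> CorrelationMatrix:
    """All-pairs Pearson r over samples (or stage means if ``stage_level``).

    Requires >= 3 observation columns.  Zero-variance genes get r = 0
    against every partner (flagged in ``constant_genes``); the diagonal is
    exactly 1 for all genes.
    """
    sub = matrix if genes is None else matrix.subset(genes)
    data = stage_means(sub) if stage_level else sub.values
    arr = data.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("Pearson correlation needs at least 3 observations")
    sd = arr.std(axis=1)
    constant = frozenset(np.asarray(data.index)[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = np.atleast_2d(r)
    r[~np.isfinite(r)] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(tuple(data.index), r, constant)


def hrr_transform(corr: CorrelationMatrix) -> np.ndarray:
    """Highest reciprocal rank matrix (integer, symmetric, diagonal 0).

    Each gene ranks all others by descending |r| (rank 1 = strongest
    partner); ties are broken by lexicographic gene-id order so the result
    is deterministic.  HRR(A, B) = max(rank_A(B), rank_B(A)), in
    [1, n - 1].
    """
    n = len(corr.gene_ids)
    if n < 3:
        raise ValueError("HRR transform needs at least 3 genes")
    absr = np.abs(corr.r).copy()
    np.fill_diagonal(absr, -np.inf)  # self never ranked
    # lexicographic gene-id position used as the deterministic tie-break
    id_pos = np.argsort(np.argsort(np.asarray(corr.gene_ids)))
    rank = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        # primary key descending |r|, secondary ascending id position
        order = np.lexsort((id_pos, -absr[i]))
        rank[i, order] = np.arange(1, n + 1)
    hrr = np.maximum(rank, rank.T)
    np.fill_diagonal(hrr, 0)
    return hrr


def build_network(
    corr: CorrelationMatrix,
    hrr: np.ndarray,
    r_min: float = 0.8,
    hrr_max: int = 30,
    weight: str = "cutoff_bin",
    tf_flags: Iterable[str] = (),
) -> nx.Graph:
    """Threshold the correlation/HRR matrices into an undirected graph.

    An edge (A, B) exists iff ``|r| >= r_min`` and ``HRR <= hrr_max``
    (both boundaries inclusive).  Edges carry ``r`` (signed), ``hrr``,
    ``weight`` and ``sign``; nodes carry an ``is_tf`` flag.  Flagged
    zero-variance genes are excluded.

    Two weight rules are available.  ``cutoff_bin`` (default) gives every
    edge the constant weight 1/(hrr_max - 5), reproducing the printed
    cutoff-to-weight mapping (10 -> 1/5, 20 -> 1/15, 30 -> 1/25); flow
    clustering then treats all admitted edges equally, which keeps dense
    co-expression groups intact.  ``inverse_hrr`` gives each edge
    weight = 1/HRR, the graph's native per-edge strength; note its heavy
    skew fragments Markov-flow clusters at high inflation.
    """
    if not (0 < r_min <= 1):
        raise ValueError("r_min must be in (0, 1]")
    if hrr_max < 1:
        raise ValueError("hrr_max must be >= 1")
    if weight == "cutoff_bin":
        const_w = 1.0 / max(hrr_max - 5, 1)
    elif weight != "inverse_hrr":
        raise ValueError(f"unknown weight rule {weight!r}")
    tf_set = set(tf_flags)
    g = nx.Graph()
    kept = [gid for gid in corr.gene_ids if gid not in corr.constant_genes]
    g.add_nodes_from((gid, {"is_tf": gid in tf_set}) for gid in kept)
    idx = {gid: i for i, gid in enumerate(corr.gene_ids)}
    for a_pos, a in enumerate(kept):
        ia = idx[a]
        for b in kept[a_pos + 1 :]:
            ib = idx[b]
            r = float(corr.r[ia, ib])
            h = int(hrr[ia, ib])
            if abs(r) >= r_min and h <= hrr_max:
                g.add_edge(
                    a,
                    b,
                    r=r,
                    hrr=h,
                    weight=const_w if weight == "cutoff_bin" else 1.0 / h,
                    sign="positive" if r > 0 else "negative",
                )
    if g.number_of_edges() == 0:
        import warnings

        warnings.warn("network has no edges at the chosen thresholds", stacklevel=2)
    return g


@dataclass(frozen=True)
class TopologyReport:
    """Whole-network summary statistics (Network Analyzer style)."""

    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    characteristic_path_length: float
    clustering_coefficient: float
    density: float
    heterogeneity: float
    centralization: float
    connected_components: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        rows = [
            ("Number of nodes", self.n_nodes),
            ("Number of edges", self.n_edges),
            ("Avg. number of neighbors", round(self.avg_neighbors, 3)),
            ("Network of diameter", self.diameter),
            ("Characteristic path length", round(self.characteristic_path_length, 3)),
            ("Clustering coefficient", round(self.clustering_coefficient, 3)),
            ("Network density", round(self.density, 3)),
            ("Network heterogeneity", round(self.heterogeneity, 3)),
            ("Network centralization", round(self.centralization, 3)),
            ("Connected components", self.connected_components),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def topology_report(g: nx.Graph) -> TopologyReport:
    """Compute the summary statistics of an undirected network.

    Path metrics (diameter, characteristic path length) are taken over
    connected pairs only, so they remain defined on fragmented networks;
    heterogeneity is sd(degree)/mean(degree) and centralization the
    Freeman degree centralization.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    avg_neighbors = 2.0 * e / n
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    clustering = float(np.mean(list(nx.clustering(g).values())))
    path_lengths: list[int] = []
    for _, targets in nx.all_pairs_shortest_path_length(g):
        path_lengths.extend(d for d in targets.values() if d > 0)
    diameter = max(path_lengths, default=0)
    cpl = float(np.mean(path_lengths)) if path_lengths else 0.0
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    if n > 2:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    else:
        centralization = 0.0
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        avg_neighbors=avg_neighbors,
        diameter=int(diameter),
        characteristic_path_length=cpl,
        clustering_coefficient=clustering,
        density=density,
        heterogeneity=heterogeneity,
        centralization=float(centralization),
        connected_components=nx.number_connected_components(g),
    )


def write_sif(g: nx.Graph, path, relation: str = "co-expr") -> None:
    """Write the edge list in Cytoscape SIF format (isolated nodes as bare rows)."""
    with open(path, "w") as handle:
        for a, b in sorted(g.edges()):
            handle.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(g.nodes()):
            if g.degree(node) == 0:
                handle.write(f"{node}\n")


def write_graphml(g: nx.Graph, path) -> None:
    """Write GraphML with r/hrr/weight/sign edge attributes (Cytoscape-compatible)."""
    nx.write_graphml(g, path)
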