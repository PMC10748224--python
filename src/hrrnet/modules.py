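"""Module assembly: cluster merging, hub/key-gene calling, TF subnetworks.

MCL tends to split one biological expression programme across several
clusters.  Clusters whose stage-expression eigenprofiles (mean of member
z-profiles) are highly correlated are therefore merged into *modules* by
average-linkage agglomeration on correlation distance.  Within a module,
genes are ranked by intramodular connectivity — the sum of 1/HRR edge
weights to other module members — to call the top hub genes and the
single key gene, and transcription factors strongly correlated with the
key genes form the TF subnetwork.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mcl import ClusterSet
from .network import CorrelationMatrix

__all__ = [
    "Module",
    "ModuleSet",
    "ModuleHubs",
    "HubReport",
    "TFSubnetwork",
    "merge_clusters",
    "intramodular_connectivity",
    "call_hubs",
    "tf_subnetwork",
]


@dataclass(frozen=True)
class Module:
    module_id: int
    cluster_ids: tuple
    genes: tuple
    mean_zprofile: tuple
    peak_stage: str


@dataclass(frozen=True)
class ModuleSet:
    """Disjoint modules over the surviving clustered genes."""

    modules: tuple
    stage_names: tuple

    @property
    def assignment(self) -> dict:
        out: dict = {}
        for mod in self.modules:
            for gene in mod.genes:
                out[gene] = mod.module_id
        return out

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [mod.mean_zprofile for mod in self.modules],
            index=[f"module_{mod.module_id}" for mod in self.modules],
            columns=list(self.stage_names),
        )


def merge_clusters(
    cs: ClusterSet,
    zprofiles: pd.DataFrame,
    merge_r: float = 0.9,
) -> ModuleSet:
    """Group clusters with similar stage-expression patterns into modules.

    Each cluster's eigenprofile is the mean of its members' z-scored
    stage profiles.  Average-linkage hierarchical clustering on
    (1 - Pearson r) between eigenprofiles is cut at distance
    ``1 - merge_r``, so merged clusters correlate at r >= merge_r at the
    linkage level.  Module ids are ordered by peak-stage index, then by
    decreasing size.
    """
    if not cs.clusters:
        return ModuleSet(modules=(), stage_names=tuple(zprofiles.columns))
    missing = {g for members in cs.clusters for g in members} - set(zprofiles.index)
    if missing:
        raise KeyError(f"clustered genes without profiles: {sorted(missing)[:5]}")
    eigen = np.vstack(
        [zprofiles.loc[list(members)].to_numpy().mean(axis=0) for members in cs.clusters]
    )
    n_clusters = eigen.shape[0]
    if n_clusters == 1:
        labels = np.array([1])
    else:
        sd = eigen.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # flat eigenprofiles correlate with nothing
        z = (eigen - eigen.mean(axis=1, keepdims=True)) / sd
        corr = np.clip(z @ z.T / eigen.shape[1], -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        dist = squareform(1.0 - corr, checks=False)
        labels = fcluster(linkage(dist, method="average"), t=1.0 - merge_r, criterion="distance")

    stage_names = tuple(zprofiles.columns)
    grouped: dict[int, list[int]] = {}
    for cidx, label in enumerate(labels):
        grouped.setdefault(int(label), []).append(cidx)

    raw_modules = []
    for cidxs in grouped.values():
        genes = sorted(g for c in cidxs for g in cs.clusters[c])
        profile = zprofiles.loc[genes].to_numpy().mean(axis=0)
        peak_idx = int(np.argmax(profile))
        raw_modules.append((peak_idx, -len(genes), tuple(sorted(i + 1 for i in cidxs)), genes, profile))
    raw_modules.sort(key=lambda t: (t[0], t[1], t[2]))
    modules = tuple(
        Module(
            module_id=mid,
            cluster_ids=cluster_ids,
            genes=tuple(genes),
            mean_zprofile=tuple(float(x) for x in profile),
            peak_stage=stage_names[peak_idx],
        )
        for mid, (peak_idx, _neg, cluster_ids, genes, profile) in enumerate(raw_modules, start=1)
    )
    return ModuleSet(modules=modules, stage_names=stage_names)


def intramodular_connectivity(
    g: nx.Graph,
    module_genes: Iterable[str],
    mode: str = "weighted",
) -> pd.Series:
    """Per-gene connectivity restricted to edges inside the module.

    ``weighted`` (default) sums 1/HRR over within-module edges (taken
    from the ``hrr`` edge attribute; edges without one contribute their
    ``weight`` attribute, default 1); ``degree`` counts within-module
    edges.  Genes with no within-module edge score 0.
    """
    if mode not in ("weighted", "degree"):
        raise ValueError("mode must be 'weighted' or 'degree'")
    members = sorted(set(module_genes))
    missing = set(members) - set(g.nodes())
    if missing:
        raise KeyError(f"module genes absent from graph: {sorted(missing)[:5]}")
    sub = g.subgraph(members)
    scores: dict = {v: 0.0 for v in members}
    for u, v, data in sub.edges(data=True):
        if mode == "degree":
            strength = 1.0
        elif "hrr" in data:
            strength = 1.0 / data["hrr"]
        else:
            strength = float(data.get("weight", 1.0))
        scores[u] += strength
        scores[v] += strength
    return pd.Series(scores, name="connectivity").loc[members]


@dataclass(frozen=True)
class ModuleHubs:
    module_id: int
    ranked_genes: tuple  # (gene, score) by rank
    hub_genes: tuple
    key_gene: str
    rank1_ties: tuple  # genes tied with the key gene on score


@dataclass(frozen=True)
class HubReport:
    per_module: tuple

    @property
    def key_genes(self) -> list:
        return [m.key_gene for m in self.per_module]

    def to_json(self) -> str:
        payload = {
            f"module_{m.module_id}": {
                "key_gene": m.key_gene,
                "hub_genes": list(m.hub_genes),
                "scores": {g: s for g, s in m.ranked_genes},
                "rank1_ties": list(m.rank1_ties),
            }
            for m in self.per_module
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def call_hubs(
    scores_by_module: Mapping[int, pd.Series],
    mean_expression: pd.Series,
    top_n: int = 10,
) -> HubReport:
    """Rank genes by connectivity within each module; call hubs and key genes.

    Ties on the connectivity score are broken by higher mean expression
    over all samples, then by gene-id order.  The hub list is the top
    ``top_n`` genes (all genes for smaller modules); the key gene is rank
    1.  Score ties at rank 1 are recorded rather than silently dropped.
    """
    per_module = []
    for module_id in sorted(scores_by_module):
        scores = scores_by_module[module_id]
        if scores.empty:
            raise ValueError(f"module {module_id} is empty")
        order = sorted(
            scores.index,
            key=lambda gene: (-scores[gene], -float(mean_expression.get(gene, 0.0)), gene),
        )
        key = order[0]
        ties = tuple(g for g in order[1:] if scores[g] == scores[key])
        per_module.append(
            ModuleHubs(
                module_id=module_id,
                ranked_genes=tuple((g, float(scores[g])) for g in order),
                hub_genes=tuple(order[: min(top_n, len(order))]),
                key_gene=key,
                rank1_ties=ties,
            )
        )
    return HubReport(per_module=tuple(per_module))


@dataclass(frozen=True)
class TFSubnetwork:
    """Key-gene/TF co-expression pairs passing the |r| threshold."""

    edges: tuple  # (key_gene, tf, r, sign)
    key_genes: tuple
    tfs: tuple

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for gene in self.key_genes:
            g.add_node(gene, role="key_gene")
        for key, tf, r, sign in self.edges:
            g.add_node(tf, role="tf")
            g.add_edge(key, tf, r=r, sign=sign)
        return g


def tf_subnetwork(
    corr: CorrelationMatrix,
    key_genes: Iterable[str],
    tf_flags: Iterable[str],
    r_min: float = 0.8,
) -> TFSubnetwork:
    """Pair each key gene with every TF correlated at |r| >= ``r_min``.

    Works on the raw correlation matrix, not the HRR-thresholded graph:
    regulatory association is judged on correlation strength alone.  A
    gene that is both a key gene and a TF is never paired with itself.
    """
    keys = sorted(set(key_genes))
    tfs = sorted(set(tf_flags) & set(corr.gene_ids))
    idx = {gid: i for i, gid in enumerate(corr.gene_ids)}
    missing = set(keys) - set(idx)
    if missing:
        raise KeyError(f"key genes absent from correlation matrix: {sorted(missing)[:5]}")
    edges = []
    linked_tfs = set()
    for key in keys:
        for tf in tfs:
            if tf == key:
                continue
            r = float(corr.r[idx[key], idx[tf]])
            if abs(r) >= r_min:
                edges.append((key, tf, r, "positive" if r > 0 else "negative"))
                linked_tfs.add(tf)
    return TFSubnetwork(
        edges=tuple(edges),
        key_genes=tuple(keys),
        tfs=tuple(sorted(linked_tfs)),
    )
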