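"""End-to-end orchestration: config, staged execution, artifacts, manifest.

The pipeline runs the full funnel — expressed-gene filter, DEG candidate
screen, Pearson correlation, HRR transform, network thresholding, MCL
clustering, enrichment-based cluster filtering, module assembly, hub and
key-gene calling, TF subnetwork extraction — writing every intermediate
artifact plus a run manifest that echoes the configuration, hashes the
inputs and records the record count after every stage.  Identical config
and inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich_cluster, results_frame
from .expression import (
    ExpressionMatrix,
    filter_expressed,
    read_deg_tsv,
    read_expression_tsv,
    read_gmt,
    read_tf_labels,
    select_candidates,
    stage_means,
    zscore_profiles,
)
from .mcl import MCLParams, drop_meaningless, mcl, write_clusters_tsv
from .modules import call_hubs, intramodular_connectivity, merge_clusters, tf_subnetwork
from .network import (
    build_network,
    hrr_transform,
    pearson_matrix,
    topology_report,
    write_graphml,
    write_sif,
)
from .synthetic import StageDesign, default_truth, write_dataset

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run", "simulate"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and keeps the cause."""


_THRESHOLD_FIELDS = {
    "fpkm_min": (0.0, float("inf")),
    "fdr_max": (0.0, 1.0),
    "lfc_min": (0.0, float("inf")),
    "r_min": (0.0, 1.0),
    "hrr_max": (1, 10**6),
    "inflation": (1.0, float("inf")),
    "merge_r": (-1.0, 1.0),
    "top_n": (1, 10**6),
    "enrich_fdr": (0.0, 1.0),
    "min_genes": (1, 10**6),
    "min_cluster_size": (1, 10**6),
    "tf_r_min": (0.0, 1.0),
}


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Defaults are the printed analysis parameters: FPKM >= 2 expression
    filter, FDR <= 0.05 and |log2FC| >= 1 DEG screen, |r| >= 0.8 with
    HRR <= 30 edges, MCL inflation 3.0, enrichment FDR < 0.05 with >= 2
    genes per term, top-10 hubs, TF linkage at |r| >= 0.8.
    """

    expression: str
    deg: str
    gmt: str
    tf: str
    out_dir: str
    extra_genes: str | None = None
    fpkm_min: float = 2.0
    stage_level_filter: bool = True
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    r_min: float = 0.8
    hrr_max: int = 30
    inflation: float = 3.0
    merge_r: float = 0.9
    top_n: int = 10
    enrich_fdr: float = 0.05
    min_genes: int = 2
    min_cluster_size: int = 3
    cluster_filter_rule: str = "or"
    weight_rule: str = "cutoff_bin"
    tf_r_min: float = 0.8
    seed: int = 1

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_FIELDS.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ValueError(f"config {name}={value} outside [{lo}, {hi}]")
        if self.cluster_filter_rule not in ("or", "and"):
            raise ValueError("cluster_filter_rule must be 'or' or 'and'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PipelineResult:
    """Everything one run produced, in memory plus on disk."""

    config: PipelineConfig
    matrix: ExpressionMatrix
    candidates: list
    corr: object
    graph: object
    topology: object
    clusters_raw: object
    clusters: object
    enrichment: pd.DataFrame
    modules: object
    hubs: object
    tf_net: object
    manifest: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_gene_list(path) -> set:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the whole pipeline and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}
    stage = "setup"

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "read_inputs"
        matrix = read_expression_tsv(config.expression)
        deg = read_deg_tsv(config.deg)
        annot_full = read_gmt(config.gmt)
        tf_labels = read_tf_labels(config.tf)
        extra = _read_gene_list(config.extra_genes) if config.extra_genes else set()
        counts["genes_total"] = len(matrix.gene_ids)

        stage = "filter_expressed"
        expressed = filter_expressed(matrix, config.fpkm_min, config.stage_level_filter)
        counts["genes_expressed"] = len(expressed.gene_ids)

        stage = "select_candidates"
        selected = select_candidates(deg, config.fdr_max, config.lfc_min, extra)
        candidates = [g for g in expressed.gene_ids if g in selected]
        counts["candidate_genes"] = len(candidates)
        with open(emit(out / "candidates.txt"), "w") as handle:
            handle.writelines(f"{g}\n" for g in candidates)
        if len(candidates) < 3:
            raise ValueError(f"only {len(candidates)} candidate genes; need >= 3")

        stage = "correlation"
        corr = pearson_matrix(expressed, candidates)
        hrr = hrr_transform(corr)

        stage = "build_network"
        graph = build_network(
            corr,
            hrr,
            r_min=config.r_min,
            hrr_max=config.hrr_max,
            weight=config.weight_rule,
            tf_flags=set(tf_labels.index),
        )
        counts["network_nodes"] = graph.number_of_nodes()
        counts["network_edges"] = graph.number_of_edges()
        write_sif(graph, emit(out / "network.sif"))
        write_graphml(graph, emit(out / "network.graphml"))

        stage = "topology"
        topo = topology_report(graph) if graph.number_of_nodes() else None
        if topo is not None:
            emit(out / "topology.json").write_text(topo.to_json() + "\n")
            emit(out / "topology.txt").write_text(topo.to_text() + "\n")

        stage = "mcl"
        clusters_raw = mcl(graph, MCLParams(inflation=config.inflation))
        counts["clusters_raw"] = len(clusters_raw.clusters)
        write_clusters_tsv(clusters_raw, emit(out / "clusters_raw.tsv"))

        stage = "enrichment"
        annot = annot_full.restrict(graph.nodes())
        all_results = []
        verdicts = {}
        for cid, members in enumerate(clusters_raw.clusters, start=1):
            res, verdict = enrich_cluster(
                cid, members, annot, config.min_genes, config.enrich_fdr
            )
            all_results.extend(res)
            verdicts[cid] = verdict
        enrichment = results_frame(all_results)
        enrichment.to_csv(
            emit(out / "enrichment.tsv"), sep="\t", index=False, float_format="%.6g"
        )

        stage = "filter_clusters"
        clusters = drop_meaningless(
            clusters_raw, verdicts, config.min_cluster_size, config.cluster_filter_rule
        )
        counts["clusters_kept"] = len(clusters.clusters)
        counts["clustered_genes"] = sum(clusters.sizes)
        write_clusters_tsv(clusters, emit(out / "clusters.tsv"))

        stage = "module_assembly"
        zprof = zscore_profiles(stage_means(expressed))
        modules = merge_clusters(clusters, zprof, config.merge_r)
        counts["modules"] = len(modules.modules)
        counts["module_genes"] = sum(len(m.genes) for m in modules.modules)
        assignment = modules.assignment
        cluster_of = clusters.assignment
        with open(emit(out / "modules.tsv"), "w") as handle:
            handle.write("gene\tcluster_id\tmodule_id\n")
            for mod in modules.modules:
                for gene in mod.genes:
                    handle.write(f"{gene}\t{cluster_of[gene]}\t{mod.module_id}\n")
        modules.profile_frame().to_csv(
            emit(out / "module_profiles.tsv"), sep="\t", float_format="%.10g"
        )

        stage = "hub_calling"
        scores = {
            mod.module_id: intramodular_connectivity(graph, mod.genes)
            for mod in modules.modules
        }
        mean_expr = expressed.values.mean(axis=1)
        hubs = call_hubs(scores, mean_expr, config.top_n) if scores else None
        counts["key_genes"] = len(hubs.key_genes) if hubs else 0
        emit(out / "hub_report.json").write_text(
            (hubs.to_json() if hubs else "{}") + "\n"
        )

        stage = "tf_subnetwork"
        tf_net = tf_subnetwork(
            corr,
            hubs.key_genes if hubs else [],
            set(tf_labels.index),
            r_min=config.tf_r_min,
        )
        counts["tf_nodes"] = tf_net.n_tfs
        counts["tf_edges"] = len(tf_net.edges)
        write_sif(tf_net.to_graph(), emit(out / "tf_subnetwork.sif"), relation="key-tf")

        stage = "manifest"
        manifest = {
            "software": {"name": "hrrnet", "version": __version__},
            "config": asdict(config),
            "inputs": {
                name: _sha256(getattr(config, name))
                for name in ("expression", "deg", "gmt", "tf")
            },
            "counts": counts,
            "mcl": {
                "iterations": clusters_raw.iterations_used,
                "converged": clusters_raw.converged,
            },
            "timestamps": {"finished_unix": int(time.time())},
        }
        # path-independent run fingerprint: artifact contents + funnel counts
        manifest["artifact_hash"] = hashlib.sha256(
            json.dumps(counts, sort_keys=True).encode()
            + b"".join(
                f"{p.name}:{_sha256(p)}".encode()
                for p in sorted(written, key=lambda q: q.name)
            )
        ).hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config=config,
        matrix=matrix,
        candidates=candidates,
        corr=corr,
        graph=graph,
        topology=topo,
        clusters_raw=clusters_raw,
        clusters=clusters,
        enrichment=enrichment,
        modules=modules,
        hubs=hubs,
        tf_net=tf_net,
        manifest=manifest,
    )


_GENERATOR_FIELDS = {
    "n_modules": 10,
    "genes_per_module": 20,
    "n_background": 100,
    "noise_sd": 0.2,
    "replicates_per_stage": 3,
    "tfs_per_module": 3,
    "terms_per_module": 2,
}


def simulate(out_dir, seed: int = 1, spec_path=None) -> dict:
    """Generate a synthetic dataset directory (four inputs + truth file).

    ``spec_path`` may point to a YAML file overriding the generator
    defaults (10 modules x 20 genes, 100 background genes, noise_sd 0.2,
    3 replicates); unknown keys are rejected.
    """
    params = dict(_GENERATOR_FIELDS)
    if spec_path is not None:
        with open(spec_path) as handle:
            payload = yaml.safe_load(handle) or {}
        unknown = set(payload) - set(params)
        if unknown:
            raise ValueError(f"{spec_path}: unknown generator key(s) {sorted(unknown)}")
        params.update(payload)
    design = StageDesign(replicates_per_stage=params.pop("replicates_per_stage"))
    truth = default_truth(design=design, seed=seed, **params)
    return write_dataset(out_dir, truth, design)
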