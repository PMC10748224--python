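"""Recovery scoring of pipeline output against planted ground truth."""

from __future__ import annotations

from typing import Mapping

from sklearn.metrics import adjusted_rand_score

from .modules import HubReport, ModuleSet
from .synthetic import SyntheticTruth

__all__ = ["module_recovery_ari", "hub_recovery", "key_gene_recovery"]


def module_recovery_ari(truth: SyntheticTruth, modules: ModuleSet) -> float:
    """Adjusted Rand index between planted and recovered module assignments.

    Scored over all planted genes: a planted gene the pipeline dropped
    (absent from every surviving module) is treated as its own singleton
    label, so losses count against the score instead of being excluded.
    """
    planted = truth.module_of
    recovered = modules.assignment
    genes = sorted(planted)
    true_labels = [planted[g] for g in genes]
    pred_labels = [recovered.get(g, f"dropped:{g}") for g in genes]
    return float(adjusted_rand_score(true_labels, pred_labels))


def hub_recovery(truth: SyntheticTruth, modules: ModuleSet, hubs: HubReport) -> dict:
    """Which planted hubs appear in the hub list of their own gene's module.

    Returns module_id -> bool over planted modules whose hub survived to
    some recovered module; hubs of fully dropped modules count as missed.
    """
    assignment = modules.assignment
    hub_lists = {m.module_id: set(m.hub_genes) for m in hubs.per_module}
    out: dict = {}
    for mod in truth.planted_modules:
        gene = mod.hub_gene
        recovered_module = assignment.get(gene)
        out[mod.module_id] = (
            recovered_module is not None and gene in hub_lists.get(recovered_module, set())
        )
    return out


def key_gene_recovery(truth: SyntheticTruth, modules: ModuleSet, hubs: HubReport) -> dict:
    """Which planted hubs were called the key gene of their recovered module."""
    assignment = modules.assignment
    key_of = {m.module_id: m.key_gene for m in hubs.per_module}
    out: dict = {}
    for mod in truth.planted_modules:
        gene = mod.hub_gene
        out[mod.module_id] = key_of.get(assignment.get(gene)) == gene
    return out
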