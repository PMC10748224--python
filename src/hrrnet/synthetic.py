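"""Synthetic staged-transcriptome generator with planted module structure.

Emulates the statistical structure the network analysis assumes: a bulk
expression matrix over ordered developmental stages with replicates, in
which planted gene modules share stage-peaked mean profiles, one member
per module adheres to the profile extra tightly (the planted hub), a
subset of members carry transcription-factor labels, and annotation
terms are preferentially assigned within modules.  Background genes get
independent random profiles.  The generator returns the planted ground
truth alongside the four input files, so recovery can be scored.

The noise model is additive Gaussian on the log scale (multiplicative on
the FPKM scale): FPKM = exp(mu_m(stage) + offset_gene + eps),
eps ~ N(0, noise_sd^2) i.i.d. per gene and sample.  All randomness flows
from one seeded generator, so a seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import AnnotationMap, ExpressionMatrix

__all__ = [
    "StageDesign",
    "PlantedModule",
    "SyntheticTruth",
    "Profile",
    "make_profiles",
    "default_truth",
    "generate_dataset",
    "write_dataset",
    "DEFAULT_STAGES",
    "TF_FAMILIES",
]

DEFAULT_STAGES = ("VS", "FI", "FM", "BS-1", "BS-2", "BS-3", "FS")
TF_FAMILIES = ("AP2/ERF", "bHLH", "CO-like", "GRAS", "MIKC", "SBP", "WRKY")

# log-scale profile geometry: baseline ~10 FPKM, 3 natural-log units of
# dynamic range so every archetype's largest adjacent-stage step clears
# the |log2FC| >= 1 screen with a wide margin
LOG_BASELINE = float(np.log(10.0))
LOG_AMPLITUDE = 3.0


@dataclass(frozen=True)
class StageDesign:
    """Ordered developmental stages and replicate count per stage."""

    stage_names: tuple = DEFAULT_STAGES
    replicates_per_stage: int = 3

    def __post_init__(self) -> None:
        if len(self.stage_names) < 2:
            raise ValueError("need at least 2 stages")
        if len(set(self.stage_names)) != len(self.stage_names):
            raise ValueError("stage names must be unique")
        if self.replicates_per_stage < 1:
            raise ValueError("need at least 1 replicate per stage")

    @property
    def n_stages(self) -> int:
        return len(self.stage_names)

    @property
    def sample_ids(self) -> list:
        return [
            f"{stage}_{rep}"
            for stage in self.stage_names
            for rep in range(1, self.replicates_per_stage + 1)
        ]


@dataclass(frozen=True)
class Profile:
    """A named archetype: per-stage expected log-expression."""

    name: str
    values: tuple

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.values))


def _shape_templates(n_stages: int) -> list:
    """Unit-scale archetype shapes for a given stage count.

    One single-stage peak per stage, plus (for >= 5 stages) an early
    plateau, a late plateau and a nondecreasing rise-to-end.  The shapes
    are designed so distinct archetypes correlate at r <= 0.5 (and
    |r| <= 0.75) on both the log and the exponentiated scale, keeping
    planted modules separable under the network's |r| >= 0.8 edge rule.
    """
    shapes: list[tuple[str, np.ndarray]] = []
    for i in range(n_stages):
        shape = np.zeros(n_stages)
        shape[i] = 1.0
        shapes.append((f"peak-stage{i}", shape))
    if n_stages >= 5:
        early = np.zeros(n_stages)
        early[:3] = 1.0
        shapes.append(("early-plateau", early))
        late = np.zeros(n_stages)
        late[n_stages - 4 : n_stages - 1] = 1.0
        shapes.append(("late-plateau", late))
        rise = np.zeros(n_stages)
        rise[-3:] = (0.967, 1.0, 1.0)
        shapes.append(("rise-to-end", rise))
    return shapes


def make_profiles(design: StageDesign, archetype_count: int) -> list:
    """Return ``archetype_count`` separable stage-profile archetypes.

    Profiles are log-scale mean vectors (baseline + amplitude * shape).
    Distinct archetypes have pairwise Pearson correlation <= 0.5.  For
    the default seven-stage design the templates carry the conventional
    names (peak-VS ... peak-FS, high-VS-FM, high-BS-1-BS-3, rise-to-FS).
    """
    shapes = _shape_templates(design.n_stages)
    if archetype_count > len(shapes):
        raise ValueError(
            f"{archetype_count} archetypes requested but only "
            f"{len(shapes)} templates exist for {design.n_stages} stages"
        )
    if design.stage_names == DEFAULT_STAGES:
        rename = {
            "peak-stage0": "peak-VS",
            "peak-stage1": "peak-FI",
            "peak-stage2": "peak-FM",
            "peak-stage3": "peak-BS-1",
            "peak-stage4": "peak-BS-2",
            "peak-stage5": "peak-BS-3",
            "peak-stage6": "peak-FS",
            "early-plateau": "high-VS-FM",
            "late-plateau": "high-BS-1-BS-3",
            "rise-to-end": "rise-to-FS",
        }
        shapes = [(rename.get(name, name), shape) for name, shape in shapes]
    out = []
    for name, shape in shapes[:archetype_count]:
        out.append(Profile(name, tuple(LOG_BASELINE + LOG_AMPLITUDE * shape)))
    if len(out) > 1:
        mat = np.array([p.values for p in out])
        corr = np.corrcoef(mat)
        iu = np.triu_indices(len(out), k=1)
        if corr[iu].max() > 0.5 + 1e-12:
            raise ValueError(
                "archetype templates for this stage count violate the "
                "pairwise r <= 0.5 separability bound"
            )
    return out


@dataclass(frozen=True)
class PlantedModule:
    """Ground-truth module: members sharing one archetype, one planted hub."""

    module_id: int
    member_genes: tuple
    mean_profile: tuple
    hub_gene: str
    tf_members: tuple = ()
    term_ids: tuple = ()

    def __post_init__(self) -> None:
        if len(self.member_genes) < 3:
            raise ValueError("planted modules need >= 3 members")
        if self.hub_gene not in self.member_genes:
            raise ValueError("hub gene must be a module member")
        if not set(self.tf_members) <= set(self.member_genes):
            raise ValueError("tf_members must be module members")


@dataclass(frozen=True)
class SyntheticTruth:
    """The generator's complete planted structure (the recovery oracle)."""

    planted_modules: tuple
    background_genes: tuple
    noise_sd: float
    seed: int
    hub_noise_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        seen: set = set()
        for mod in self.planted_modules:
            overlap = seen & set(mod.member_genes)
            if overlap:
                raise ValueError(f"overlapping planted memberships: {sorted(overlap)[:5]}")
            seen |= set(mod.member_genes)
        if seen & set(self.background_genes):
            raise ValueError("background genes overlap planted modules")

    @property
    def all_genes(self) -> list:
        genes = [g for m in self.planted_modules for g in m.member_genes]
        genes.extend(self.background_genes)
        return genes

    @property
    def module_of(self) -> dict:
        return {
            g: m.module_id for m in self.planted_modules for g in m.member_genes
        }

    @property
    def hub_genes(self) -> dict:
        return {m.module_id: m.hub_gene for m in self.planted_modules}

    def to_json(self) -> str:
        payload = {
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "hub_noise_factor": self.hub_noise_factor,
            "background_genes": list(self.background_genes),
            "planted_modules": [
                {
                    "module_id": m.module_id,
                    "member_genes": list(m.member_genes),
                    "mean_profile": list(m.mean_profile),
                    "hub_gene": m.hub_gene,
                    "tf_members": list(m.tf_members),
                    "term_ids": list(m.term_ids),
                }
                for m in self.planted_modules
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        modules = tuple(
            PlantedModule(
                module_id=m["module_id"],
                member_genes=tuple(m["member_genes"]),
                mean_profile=tuple(m["mean_profile"]),
                hub_gene=m["hub_gene"],
                tf_members=tuple(m["tf_members"]),
                term_ids=tuple(m["term_ids"]),
            )
            for m in payload["planted_modules"]
        )
        return cls(
            planted_modules=modules,
            background_genes=tuple(payload["background_genes"]),
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
            hub_noise_factor=payload["hub_noise_factor"],
        )


def default_truth(
    design: StageDesign = StageDesign(),
    n_modules: int = 10,
    genes_per_module: int = 20,
    n_background: int = 100,
    noise_sd: float = 0.2,
    seed: int = 1,
    tfs_per_module: int = 3,
    terms_per_module: int = 2,
) -> SyntheticTruth:
    """Build the standard benchmark truth: 10 modules x 20 genes + 100 background."""
    rng = np.random.default_rng(seed)
    profiles = make_profiles(design, n_modules)
    modules = []
    for m, profile in enumerate(profiles, start=1):
        members = tuple(f"gene_m{m:02d}_{i:02d}" for i in range(1, genes_per_module + 1))
        hub = str(rng.choice(members))
        tfs = tuple(sorted(rng.choice(members, size=min(tfs_per_module, len(members)), replace=False)))
        terms = tuple(f"TERM:{m:04d}{chr(ord('a') + t)}" for t in range(terms_per_module))
        modules.append(
            PlantedModule(
                module_id=m,
                member_genes=members,
                mean_profile=profile.values,
                hub_gene=hub,
                tf_members=tfs,
                term_ids=terms,
            )
        )
    background = tuple(f"gene_bg_{i:03d}" for i in range(1, n_background + 1))
    return SyntheticTruth(
        planted_modules=tuple(modules),
        background_genes=background,
        noise_sd=noise_sd,
        seed=seed,
    )


def _adjacent_comparisons(design: StageDesign) -> list:
    names = design.stage_names
    return [(names[i], names[i + 1]) for i in range(len(names) - 1)]


def generate_dataset(
    truth: SyntheticTruth,
    design: StageDesign = StageDesign(),
) -> tuple:
    """Draw the four analysis inputs from the planted truth.

    Returns ``(ExpressionMatrix, deg_table, AnnotationMap, tf_labels)``.
    Member genes share their module's log-profile up to a gene-specific
    offset; the planted hub's noise is scaled by ``hub_noise_factor`` so
    its tighter profile adherence surfaces as the highest connectivity.
    The DEG table holds realized stage-mean log2 ratios for adjacent
    stages, with a synthetic FDR column tied to the *true* profile steps
    so that every planted gene passes the screen somewhere.
    """
    rng = np.random.default_rng(truth.seed)
    stages = design.stage_names
    n_stages = design.n_stages
    reps = design.replicates_per_stage
    for mod in truth.planted_modules:
        if len(mod.mean_profile) != n_stages:
            raise ValueError(
                f"module {mod.module_id} profile length {len(mod.mean_profile)} "
                f"!= {n_stages} stages"
            )

    genes = truth.all_genes
    log_mu = np.empty((len(genes), n_stages))
    noise_scale = np.full(len(genes), truth.noise_sd)
    row = {g: i for i, g in enumerate(genes)}
    for mod in truth.planted_modules:
        profile = np.asarray(mod.mean_profile)
        for g in mod.member_genes:
            log_mu[row[g]] = profile + rng.normal(0.0, 0.3)  # gene offset
        noise_scale[row[mod.hub_gene]] *= truth.hub_noise_factor
    for g in truth.background_genes:
        log_mu[row[g]] = LOG_BASELINE + rng.normal(0.0, 1.0, size=n_stages)

    eps = rng.normal(0.0, 1.0, size=(len(genes), n_stages * reps))
    eps *= noise_scale[:, None]
    values = np.exp(np.repeat(log_mu, reps, axis=1) + eps)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=design.sample_ids),
        tuple(stages),
    )

    # DEG table: realized stage-mean log2 ratios; synthetic FDR anchored
    # to the true profile so truly-changed rows are confidently small
    stage_mean = values.reshape(len(genes), n_stages, reps).mean(axis=2)
    stage_idx = {s: i for i, s in enumerate(stages)}
    deg_rows = []
    for a, b in _adjacent_comparisons(design):
        ia, ib = stage_idx[a], stage_idx[b]
        lfc = np.log2(stage_mean[:, ib] / stage_mean[:, ia])
        true_step = np.abs(log_mu[:, ib] - log_mu[:, ia]) / np.log(2.0)
        changed = true_step >= 1.0
        fdr = np.where(
            changed,
            10.0 ** rng.uniform(-8.0, -3.0, size=len(genes)),
            rng.uniform(0.06, 1.0, size=len(genes)),
        )
        for gi, g in enumerate(genes):
            deg_rows.append((g, f"{a}_vs_{b}", float(lfc[gi]), float(fdr[gi])))
    deg = pd.DataFrame(deg_rows, columns=["gene", "comparison", "log2fc", "fdr"])

    # annotation map: each module's terms cover 90% of members, 2% of others
    term_genes: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    gene_arr = np.asarray(genes)
    for mod in truth.planted_modules:
        members = np.asarray(mod.member_genes)
        outsiders = gene_arr[~np.isin(gene_arr, members)]
        for term in mod.term_ids:
            n_in = max(int(np.ceil(0.9 * len(members))), 2)
            inside = rng.choice(members, size=n_in, replace=False)
            n_out = int(round(0.02 * len(outsiders)))
            outside = rng.choice(outsiders, size=n_out, replace=False) if n_out else []
            term_genes[term] = set(inside) | set(outside)
            descriptions[term] = f"planted term of module {mod.module_id}"
    for t in ("TERM:bg01", "TERM:bg02"):
        term_genes[t] = set(rng.choice(gene_arr, size=max(len(genes) // 10, 2), replace=False))
        descriptions[t] = "unstructured background term"
    annot = AnnotationMap.from_sets(term_genes, genes, descriptions)

    # TF labels: module tf_members plus ~10 background TFs
    tf_rows = []
    for mod in truth.planted_modules:
        for g in mod.tf_members:
            tf_rows.append((g, TF_FAMILIES[int(rng.integers(len(TF_FAMILIES)))]))
    n_bg_tf = min(10, len(truth.background_genes))
    if n_bg_tf:
        for g in sorted(rng.choice(np.asarray(truth.background_genes), size=n_bg_tf, replace=False)):
            tf_rows.append((g, TF_FAMILIES[int(rng.integers(len(TF_FAMILIES)))]))
    tf_labels = pd.Series(
        [fam for _, fam in tf_rows],
        index=[g for g, _ in tf_rows],
        name="family",
    )
    return matrix, deg, annot, tf_labels


def write_dataset(
    out_dir,
    truth: SyntheticTruth,
    design: StageDesign = StageDesign(),
) -> dict:
    """Generate and write the four inputs plus the truth file; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, deg, annot, tfs = generate_dataset(truth, design)
    paths = {
        "expression": out / "expression.tsv",
        "deg": out / "deg_table.tsv",
        "gmt": out / "annotations.gmt",
        "tf": out / "tf_labels.tsv",
        "truth": out / "truth.json",
    }
    matrix.to_tsv(paths["expression"])
    deg.to_csv(paths["deg"], sep="\t", index=False, float_format="%.10g")
    with open(paths["gmt"], "w") as handle:
        for term in sorted(annot.terms):
            members = "\t".join(sorted(annot.terms[term]))
            handle.write(f"{term}\t{annot.descriptions[term]}\t{members}\n")
    with open(paths["tf"], "w") as handle:
        handle.write("gene\tfamily\n")
        for gene in tfs.index:
            handle.write(f"{gene}\t{tfs[gene]}\n")
    with open(paths["truth"], "w") as handle:
        handle.write(truth.to_json())
        handle.write("\n")
    return {k: str(v) for k, v in paths.items()}
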