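"""Expression-matrix I/O, screening filters and stage-level summaries.

The pipeline's universal input is a gene x sample matrix of nonnegative
FPKM-like values whose sample names encode the developmental stage and
replicate (``<stage>_<replicate>``, e.g. ``FI_2``).  This module reads and
validates that matrix together with the differential-expression statistics
table, the GMT annotation map and transcription-factor labels, applies the
expressed-gene and DEG screens, and computes per-stage mean / z-scored
profiles used downstream for module assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "AnnotationMap",
    "QPCRRecord",
    "read_expression_tsv",
    "read_deg_tsv",
    "read_gmt",
    "read_tf_labels",
    "filter_expressed",
    "select_candidates",
    "stage_means",
    "zscore_profiles",
    "ddct_fold_change",
    "validate_against_qpcr",
]

DEG_COLUMNS = ("gene", "comparison", "log2fc", "fdr")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _split_sample(sample_id: str) -> tuple[str, str]:
    stage, sep, rep = sample_id.rpartition("_")
    if not sep or not stage or not rep:
        raise FormatError(
            f"sample id {sample_id!r} does not follow '<stage>_<replicate>'"
        )
    return stage, rep


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample nonnegative expression values with stage metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample; sample
        names must follow ``<stage>_<replicate>``.
    """

    values: pd.DataFrame
    stage_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if (v.to_numpy() < 0).any():
            raise FormatError("expression values must be nonnegative")
        stages = [_split_sample(s)[0] for s in v.columns]
        if not self.stage_order:
            seen: dict[str, None] = {}
            for s in stages:
                seen.setdefault(s, None)
            object.__setattr__(self, "stage_order", tuple(seen))
        else:
            unknown = set(stages) - set(self.stage_order)
            if unknown:
                raise FormatError(f"samples reference unknown stages: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_stages(self) -> pd.Series:
        return pd.Series(
            [_split_sample(s)[0] for s in self.values.columns],
            index=self.values.columns,
            name="stage",
        )

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.stage_order)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_expression_tsv(path, stage_order: Sequence[str] = ()) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = gene id, header = sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric expression column(s) {non_numeric}")
    return ExpressionMatrix(df.astype(float), tuple(stage_order))


def read_deg_tsv(path) -> pd.DataFrame:
    """Read the differential-expression table (gene, comparison, log2fc, fdr)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing DEG column(s) {missing}")
    df = df.loc[:, list(DEG_COLUMNS)].copy()
    df["log2fc"] = df["log2fc"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    bad = df.index[(df["fdr"] < 0) | (df["fdr"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: FDR outside [0, 1] at data row {bad[0] + 2}")
    return df


@dataclass(frozen=True)
class AnnotationMap:
    """Annotation term -> gene-set mapping with a background universe.

    Term gene sets are stored intersected with the universe; terms that
    become empty after intersection are dropped.
    """

    terms: Mapping[str, frozenset]
    descriptions: Mapping[str, str]
    universe: frozenset

    @classmethod
    def from_sets(
        cls,
        term_genes: Mapping[str, Iterable[str]],
        universe: Iterable[str],
        descriptions: Mapping[str, str] | None = None,
    ) -> "AnnotationMap":
        uni = frozenset(universe)
        terms: dict[str, frozenset] = {}
        descs: dict[str, str] = {}
        for term, genes in term_genes.items():
            kept = frozenset(genes) & uni
            if kept:
                terms[term] = kept
                descs[term] = (descriptions or {}).get(term, "")
        return cls(terms, descs, uni)

    def restrict(self, universe: Iterable[str]) -> "AnnotationMap":
        """Re-scope the map to a new universe (e.g. the genes in the network)."""
        return AnnotationMap.from_sets(self.terms, universe, self.descriptions)

    def genes_with_term(self, term: str) -> frozenset:
        return self.terms.get(term, frozenset())


def read_gmt(path, universe: Iterable[str] | None = None) -> AnnotationMap:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    term_genes: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    all_genes: set = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'term<TAB>description<TAB>genes...'"
                )
            term, desc, *genes = fields
            if term in term_genes:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = [g for g in genes if g]
            term_genes[term] = set(genes)
            descriptions[term] = desc
            all_genes.update(genes)
    return AnnotationMap.from_sets(
        term_genes, all_genes if universe is None else universe, descriptions
    )


def read_tf_labels(path) -> pd.Series:
    """Read TF labels TSV (columns: gene, family) into a gene -> family Series."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "family"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate TF gene {dup!r}")
    return pd.Series(df["family"].to_numpy(), index=df["gene"], name="family")


# ---------------------------------------------------------------------------
# Screens and summaries
# ---------------------------------------------------------------------------


def filter_expressed(
    matrix: ExpressionMatrix,
    threshold: float = 2.0,
    stage_level: bool = True,
) -> ExpressionMatrix:
    """Keep genes expressed above ``threshold`` in at least one transcriptome.

    With ``stage_level=True`` (default) a gene is expressed if any *stage
    mean* reaches the threshold — one transcriptome per stage condition;
    with ``stage_level=False`` any single sample suffices.  Gene order is
    preserved.  An empty result is legal and only warns.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if stage_level:
        level = stage_means(matrix)
    else:
        level = matrix.values
    keep = (level >= threshold).any(axis=1)
    if not keep.any():
        import warnings

        warnings.warn("no gene passed the expression filter", stacklevel=2)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.stage_order)


def select_candidates(
    deg: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    extra: Iterable[str] = (),
) -> set:
    """Select DEGs pooled over all comparisons, plus curated ``extra`` genes.

    A gene qualifies if any row has ``fdr <= fdr_max`` and
    ``|log2fc| >= lfc_min`` (both boundaries inclusive, as printed).
    """
    if fdr_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    passed = deg.loc[(deg["fdr"] <= fdr_max) & (deg["log2fc"].abs() >= lfc_min), "gene"]
    return set(passed) | set(extra)


def stage_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean over replicates per stage; genes x stages."""
    stages = matrix.sample_stages
    out = matrix.values.T.groupby(stages, sort=False).mean().T
    return out.loc[:, list(matrix.stage_order)]


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's stage profile (population sd; sd = 0 -> all zeros)."""
    arr = profiles.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (ddof=0), held fixed
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mu) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


# ---------------------------------------------------------------------------
# qPCR validation utilities (2^-ddCt)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QPCRRecord:
    """Per-sample Ct values for a target gene and the reference gene.

    ``ct_target`` and ``ct_reference`` map sample id -> cycle threshold;
    ``calibrator`` names the sample all fold changes are normalised to.
    """

    gene_id: str
    ct_target: Mapping[str, float]
    ct_reference: Mapping[str, float]
    calibrator: str

    def __post_init__(self) -> None:
        if self.calibrator not in self.ct_target:
            raise ValueError(f"calibrator sample {self.calibrator!r} missing")
        for sample in self.ct_target:
            if sample not in self.ct_reference:
                raise ValueError(f"reference Ct missing for sample {sample!r}")
        for mapping in (self.ct_target, self.ct_reference):
            for sample, ct in mapping.items():
                if not math.isfinite(ct):
                    raise ValueError(f"non-finite Ct for sample {sample!r}")


def ddct_fold_change(rec: QPCRRecord) -> pd.Series:
    """Relative expression per sample by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference; ddCt = dCt_sample - dCt_calibrator;
    fold change = 2^-ddCt (1 at the calibrator by construction).
    """
    dct = {s: rec.ct_target[s] - rec.ct_reference[s] for s in rec.ct_target}
    dct_cal = dct[rec.calibrator]
    fc = {s: 2.0 ** -(v - dct_cal) for s, v in dct.items()}
    return pd.Series(fc, name=rec.gene_id)


def validate_against_qpcr(
    fold_changes: Mapping[str, pd.Series],
    matrix: ExpressionMatrix,
    genes: Iterable[str] | None = None,
) -> pd.Series:
    """Pearson r between stage-mean FPKM and stage-mean qPCR fold change.

    Fold-change series are indexed by sample id; both series are averaged
    to stage level over the stages they share (>= 3 required).  A
    zero-variance series yields an undefined r, reported as NaN.
    """
    means = stage_means(matrix)
    out: dict[str, float] = {}
    for gene in genes if genes is not None else fold_changes:
        fc = fold_changes[gene]
        fc_stage = fc.groupby(fc.index.map(lambda s: _split_sample(s)[0])).mean()
        common = [s for s in matrix.stage_order if s in fc_stage.index]
        if len(common) < 3:
            raise ValueError(f"gene {gene!r}: fewer than 3 stages in common")
        x = means.loc[gene, common].to_numpy(dtype=float)
        y = fc_stage.loc[common].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[gene] = float("nan")
        else:
            out[gene] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")
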