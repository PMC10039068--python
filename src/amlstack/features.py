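"""Per-drug genomic feature construction.

Features combine AML-context-driven gene selections (molecular-subtype
genes, pathway activation scores over mutated genes, drug-target genes
and their network neighbourhood, mutated genes, curated AML-relevant
genes) with data-driven selections (highest-variance genes and genes
most correlated with the drug's response), followed by a Spearman
redundancy filter (|rho| > 0.90 drops the later feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    DegenerateSampleError,
    DrugTargetMap,
    ExpressionMatrix,
    FunctionalNetwork,
    GeneSetCollection,
    InsufficientDataError,
    MutationProfile,
    ValidationError,
)

logger = logging.getLogger("amlstack")


def default_aml_relevant_genes() -> list[str]:
    """The bundled default AML-relevant gene list.

    A small curated convenience list of genes recurrently implicated in
    AML (driver mutations, fusions, survival machinery).  It is not a
    canonical signature; supply a study-specific GMT where it matters.
    """
    from pathlib import Path

    from .io import read_gmt

    path = Path(__file__).parent / "data" / "aml_relevant_default.gmt"
    return read_gmt(path)["AML_RELEVANT_DEFAULT"]


#: fixed source precedence: context-driven first, then data-driven.
SOURCE_ORDER = (
    "subtype",
    "pas",
    "drug_targets",
    "mutated",
    "aml_relevant",
    "high_variance",
    "correlated",
)


@dataclass
class FeatureSpec:
    """Tunable knobs of feature construction.

    Defaults mirror the published pipeline: 15 top genes per molecular
    subtype, 100 highest-variance genes, 100 response-correlated genes,
    and a |rho| > 0.90 Spearman redundancy cutoff.
    """

    subtype_top_k: int = 15
    variance_top_k: int = 100
    correlation_top_k: int = 100
    redundancy_rho: float = 0.90
    feature_sources: tuple[str, ...] = SOURCE_ORDER
    pas_mode: str = "mean"  # or "sum"

    def __post_init__(self) -> None:
        if min(self.subtype_top_k, self.variance_top_k, self.correlation_top_k) < 1:
            raise ValidationError("all top-k values must be >= 1")
        if not (0 < self.redundancy_rho <= 1):
            raise ValidationError("redundancy_rho must be in (0, 1]")
        unknown = set(self.feature_sources) - set(SOURCE_ORDER)
        if unknown:
            raise ValidationError(f"unknown feature sources {sorted(unknown)}")
        if self.pas_mode not in ("mean", "sum"):
            raise ValidationError("pas_mode must be 'mean' or 'sum'")

    def to_dict(self) -> dict:
        return {
            "subtype_top_k": self.subtype_top_k,
            "variance_top_k": self.variance_top_k,
            "correlation_top_k": self.correlation_top_k,
            "redundancy_rho": self.redundancy_rho,
            "feature_sources": list(self.feature_sources),
            "pas_mode": self.pas_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        d = dict(d)
        if "feature_sources" in d:
            d["feature_sources"] = tuple(d["feature_sources"])
        return cls(**d)


@dataclass
class FeatureMatrix:
    """Samples x features values with per-feature provenance tags."""

    values: pd.DataFrame  # index = samples, columns = features
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate feature names")
        missing = set(self.values.columns) - set(self.provenance)
        if missing:
            raise ValidationError(f"features without provenance: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")
        if sidecar_path is not None:
            pd.Series(self.provenance, name="source").rename_axis("feature").to_csv(
                sidecar_path, sep="\t"
            )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_expression(
    expr: ExpressionMatrix, per_gene: bool = False
) -> ExpressionMatrix:
    """Median-center and scale to unit variance (median = 0, sd = 1).

    Per sample (column) by default, matching the published pipeline; a
    per-gene option exists for other normalization conventions.
    """
    df = expr.data.T if per_gene else expr.data
    med = df.median(axis=0)
    centered = df - med
    sd = centered.std(axis=0, ddof=1)
    degenerate = sd[(sd == 0) | sd.isna()]
    if len(degenerate):
        name = degenerate.index[0]
        raise DegenerateSampleError(
            f"constant {'gene' if per_gene else 'sample'} column {name!r} "
            "cannot be normalized"
        )
    out = centered / sd
    return ExpressionMatrix(out.T if per_gene else out)


# ---------------------------------------------------------------------------
# Gene selections
# ---------------------------------------------------------------------------


def select_subtype_genes(collection: GeneSetCollection, k: int = 15) -> list[str]:
    """Union of the first ``k`` genes of every (rank-ordered) subtype set,
    deduplicated preserving first occurrence."""
    seen: dict[str, None] = {}
    for name in collection.names():
        for g in collection[name][:k]:
            seen.setdefault(g, None)
    return list(seen)


def compute_pas(
    expr_norm: ExpressionMatrix,
    pathways: GeneSetCollection,
    mutated_genes: list[str],
    mode: str = "mean",
) -> FeatureMatrix:
    """Pathway activation scores over pathways touched by somatic mutations.

    Only pathways containing at least one mutated gene are scored; the
    score is the mean (or sum) normalized expression of the pathway's
    member genes present in the matrix.
    """
    mut = set(mutated_genes)
    values: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    gene_index = set(expr_norm.data.index)
    for name in pathways.names():
        members = pathways[name]
        if not mut.intersection(members):
            continue
        measured = [g for g in members if g in gene_index]
        if not measured:
            logger.warning("pathway %s has no measured member genes; dropped", name)
            continue
        block = expr_norm.data.loc[measured]
        score = block.sum(axis=0) if mode == "sum" else block.mean(axis=0)
        feat = f"PAS:{name}"
        values[feat] = score.to_numpy()
        provenance[feat] = "pas"
    df = pd.DataFrame(values, index=expr_norm.samples)
    return FeatureMatrix(df, provenance)


def drug_context_genes(
    drug: str, targets: DrugTargetMap, network: FunctionalNetwork
) -> list[str]:
    """A drug's primary targets plus their 1-hop network neighbours,
    approximating the up-/downstream regulatory context of the targets."""
    out: dict[str, None] = {}
    for t in targets.get(drug):
        out.setdefault(t, None)
    for t in targets.get(drug):
        for nb in network.neighbors(t):
            out.setdefault(nb, None)
    return list(out)


def select_high_variance_genes(expr_norm: ExpressionMatrix, k: int = 100) -> list[str]:
    """The ``k`` genes with the largest across-sample variance; ties broken
    toward the lexicographically smaller symbol."""
    var = expr_norm.data.var(axis=1, ddof=1)
    if k > len(var):
        logger.warning("requested %d high-variance genes, only %d available", k, len(var))
        k = len(var)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:k]


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def spearman_safe(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average-rank ties; 0 when either vector is constant."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def select_correlated_genes(
    expr_norm: ExpressionMatrix, response: pd.Series, k: int = 100
) -> list[str]:
    """The ``k`` genes whose expression is most |Spearman|-correlated with
    the drug's observed response; constant genes rank last (rho = 0)."""
    common = [s for s in expr_norm.samples if s in response.index]
    common = [s for s in common if np.isfinite(response[s])]
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} samples with both expression and response"
        )
    X = expr_norm.data[common].to_numpy()  # genes x n
    y = response[common].to_numpy(dtype=float)
    ry = _rank(y)
    rX = _rank(X)
    rX_c = rX - rX.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rX_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rX_c @ ry_c) / denom
    rho = np.nan_to_num(rho, nan=0.0)
    genes = expr_norm.genes
    order = sorted(range(len(genes)), key=lambda i: (-abs(rho[i]), genes[i]))
    k = min(k, len(genes))
    return [genes[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# Redundancy filter
# ---------------------------------------------------------------------------


def redundancy_filter(features: FeatureMatrix, rho: float = 0.90) -> FeatureMatrix:
    """Greedy scan in feature order: drop any feature with |Spearman rho|
    above the cutoff against an already-retained feature."""
    df = features.values
    if df.shape[1] <= 1:
        return features
    if df.shape[0] < 2:
        raise InsufficientDataError("redundancy filter needs >= 2 samples")
    X = df.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=0)
    rc = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((rc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (rc.T @ rc) / np.outer(norms, norms)
    corr = np.nan_to_num(corr, nan=0.0)  # constant feature: rho treated as 0
    keep: list[int] = []
    for j in range(df.shape[1]):
        if all(abs(corr[j, i]) <= rho for i in keep):
            keep.append(j)
    cols = [df.columns[j] for j in keep]
    return FeatureMatrix(
        df[cols], {c: features.provenance[c] for c in cols}
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortInputs:
    """Bundle of the per-cohort inputs feature assembly draws from."""

    expr_norm: ExpressionMatrix
    mutations: MutationProfile | None = None
    subtype_sets: GeneSetCollection | None = None
    pathway_sets: GeneSetCollection | None = None
    aml_relevant_genes: list[str] | None = None
    drug_targets: DrugTargetMap | None = None
    network: FunctionalNetwork | None = None


def assemble_features(
    cohort: CohortInputs,
    spec: FeatureSpec,
    drug: str | None = None,
    response: pd.Series | None = None,
) -> FeatureMatrix:
    """Build the full feature matrix for one drug (or drug-agnostic when
    ``drug`` is None, as used by the subtype classifier).

    Sources are concatenated in fixed precedence order, deduplicated by
    gene with first-source provenance, then redundancy-filtered.
    """
    expr = cohort.expr_norm
    gene_index = set(expr.data.index)
    enabled = [s for s in SOURCE_ORDER if s in spec.feature_sources]

    gene_features: dict[str, str] = {}  # gene -> source (first wins)

    def add_genes(genes: list[str], source: str) -> None:
        for g in sorted(set(genes) & gene_index):
            gene_features.setdefault(g, source)

    pas_fm: FeatureMatrix | None = None
    for source in enabled:
        if source == "subtype" and cohort.subtype_sets is not None:
            add_genes(
                select_subtype_genes(cohort.subtype_sets, spec.subtype_top_k),
                "subtype",
            )
        elif source == "pas" and cohort.pathway_sets is not None:
            mutated = (
                cohort.mutations.mutated_genes() if cohort.mutations is not None else []
            )
            pas_fm = compute_pas(expr, cohort.pathway_sets, mutated, spec.pas_mode)
        elif source == "drug_targets" and drug is not None:
            if cohort.drug_targets is not None and cohort.network is not None:
                add_genes(
                    drug_context_genes(drug, cohort.drug_targets, cohort.network),
                    "drug_targets",
                )
        elif source == "mutated" and cohort.mutations is not None:
            add_genes(cohort.mutations.mutated_genes(), "mutated")
        elif source == "aml_relevant" and cohort.aml_relevant_genes is not None:
            add_genes(cohort.aml_relevant_genes, "aml_relevant")
        elif source == "high_variance":
            add_genes(select_high_variance_genes(expr, spec.variance_top_k), "high_variance")
        elif source == "correlated" and drug is not None and response is not None:
            add_genes(
                select_correlated_genes(expr, response, spec.correlation_top_k),
                "correlated",
            )

    # order: source precedence, lexicographic within source
    src_rank = {s: i for i, s in enumerate(SOURCE_ORDER)}
    ordered = sorted(gene_features, key=lambda g: (src_rank[gene_features[g]], g))
    blocks = []
    provenance = {}
    if ordered:
        gene_block = expr.data.loc[ordered].T
        blocks.append(gene_block)
        provenance.update({g: gene_features[g] for g in ordered})
    if pas_fm is not None and pas_fm.values.shape[1]:
        blocks.append(pas_fm.values)
        provenance.update(pas_fm.provenance)
    if not blocks:
        raise ValidationError(f"no features could be assembled for drug {drug!r}")
    merged = pd.concat(blocks, axis=1)
    # re-order columns to precedence order for the greedy redundancy scan
    cols = sorted(merged.columns, key=lambda c: (src_rank[provenance[c]], c))
    fm = FeatureMatrix(merged[cols], provenance)
    fm = redundancy_filter(fm, spec.redundancy_rho)
    if not fm.features:
        raise ValidationError(f"feature set empty after redundancy filter ({drug!r})")
    return fm
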