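"""Seeded synthetic AML cohort generator.

Real training cohorts for this problem are access-controlled, so every
module is exercised on generated cohorts carrying the statistical
structure the method exploits:

* subtype mean-shift structure in expression,
* per-drug responses driven by planted signal genes, with a shared
  gene-driven factor inducing a target correlation between drugs that
  share target genes,
* a monotone affine IC50-AUC relationship per drug (so the AUC
  good-response threshold is recoverable), with a ceiling at IC50 = 10
  applied to a configurable fraction of records,
* screens missing completely at random,
* center IDs for center-disjoint splitting.

Ground truth (signal genes, latent responses, true thresholds) is
returned so recovery tests can score the pipeline against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CohortInputs, normalize_expression
from .io import (
    DrugResponseTable,
    DrugTargetMap,
    ExpressionMatrix,
    FunctionalNetwork,
    GeneSetCollection,
    MutationProfile,
    network_from_edges,
    write_drug_response,
    write_drug_targets,
    write_expression,
    write_gmt,
    write_mutations,
    write_network,
)

AUC_CENTER = 150.0
AUC_SCALE = 40.0


@dataclass
class CohortSpec:
    """Generation parameters; generation is fully determined by spec+seed."""

    n_patients: int = 200
    n_genes: int = 400
    n_drugs: int = 10
    n_subtypes: int = 4
    n_centers: int = 5
    cross_drug_rho: float = 0.8
    signal_genes_per_drug: int = 5
    noise_sd: float = 0.3
    missing_screen_fraction: float = 0.3
    ic50_slope: float = 1.5
    ic50_intercept: float = 2.0
    ic50_ceiling_fraction: float = 0.4
    ic50_noise_sd: float = 0.15
    drug_mean_sd: float = 20.0  # between-drug spread of mean AUC
    subtype_separation: float = 3.0
    genes_per_subtype: int = 10
    n_mutated_genes: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients, self.n_genes, self.n_drugs,
            self.n_subtypes, self.n_centers, self.signal_genes_per_drug,
        )
        if min(counts) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.missing_screen_fraction < 1):
            raise ValueError("missing_screen_fraction must be in [0, 1)")
        if not (0 <= self.ic50_ceiling_fraction < 1):
            raise ValueError("ic50_ceiling_fraction must be in [0, 1)")
        if not (0 <= self.cross_drug_rho < 1):
            raise ValueError("cross_drug_rho must be in [0, 1)")
        if self.cross_drug_rho + self.noise_sd**2 > 1:
            raise ValueError("cross_drug_rho + noise_sd^2 must be <= 1")
        n_groups = (self.n_drugs + 1) // 2
        needed = (
            self.n_subtypes * self.genes_per_subtype
            + n_groups * self.signal_genes_per_drug
            + self.n_drugs * self.signal_genes_per_drug
            + self.n_mutated_genes
        )
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the planted structure "
                f"(needs >= {needed})"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    signal_genes: dict[str, list[str]]  # drug -> shared + private genes
    shared_genes: dict[int, list[str]]  # target group -> shared genes
    groups: dict[str, int]  # drug -> target group
    latent: pd.DataFrame  # patients x drugs standardized response
    thresholds: dict[str, float]  # drug -> true T_AUC at IC50 = 1
    subtype_genes: dict[str, list[str]]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # raw, CPM-like
    mutations: MutationProfile
    responses: DrugResponseTable
    subtype_labels: pd.Series
    centers: pd.Series
    subtype_sets: GeneSetCollection
    pathway_sets: GeneSetCollection
    aml_relevant_genes: list[str]
    drug_targets: DrugTargetMap
    network: FunctionalNetwork
    truth: GroundTruth = field(repr=False, default=None)

    def cohort_inputs(self, samples: list[str] | None = None) -> CohortInputs:
        """Normalized-expression input bundle for the modelling modules."""
        expr = self.expression
        if samples is not None:
            expr = ExpressionMatrix(expr.data[samples])
        mut = self.mutations
        if samples is not None:
            mut = MutationProfile(mut.data.loc[samples])
        return CohortInputs(
            expr_norm=normalize_expression(expr),
            mutations=mut,
            subtype_sets=self.subtype_sets,
            pathway_sets=self.pathway_sets,
            aml_relevant_genes=self.aml_relevant_genes,
            drug_targets=self.drug_targets,
            network=self.network,
        )

    def responses_for(self, samples: list[str]) -> DrugResponseTable:
        rec = self.responses.records
        return DrugResponseTable(
            rec[rec["sample"].isin(samples)].reset_index(drop=True)
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression(self.expression, outdir / "expression.tsv")
        write_mutations(self.mutations, outdir / "mutations.tsv")
        write_drug_response(self.responses, outdir / "responses.tsv")
        write_gmt(self.subtype_sets, outdir / "subtype_sets.gmt")
        write_gmt(self.pathway_sets, outdir / "pathways.gmt")
        write_drug_targets(self.drug_targets, outdir / "drug_targets.tsv")
        write_network(self.network, outdir / "network.tsv")
        self.subtype_labels.rename("subtype").rename_axis("sample").to_csv(
            outdir / "subtypes.tsv", sep="\t"
        )
        self.centers.rename("center").rename_axis("sample").to_csv(
            outdir / "centers.tsv", sep="\t"
        )
        with open(outdir / "aml_relevant.gmt", "w") as fh:
            fh.write("\t".join(["AML_RELEVANT", "synthetic", *self.aml_relevant_genes]) + "\n")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort with planted, recoverable structure."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    patients = [f"p{i:03d}" for i in range(spec.n_patients)]
    drugs = [f"d{i:02d}" for i in range(spec.n_drugs)]
    subtype_names = [f"ST{i + 1}" for i in range(spec.n_subtypes)]

    # --- disjoint gene blocks for the planted structure
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor: cursor + n]
        cursor += n
        return block

    subtype_genes = {st: take(spec.genes_per_subtype) for st in subtype_names}
    n_groups = (spec.n_drugs + 1) // 2
    shared_genes = {g: take(spec.signal_genes_per_drug) for g in range(n_groups)}
    private_genes = {d: take(spec.signal_genes_per_drug) for d in drugs}
    mutated_genes = take(spec.n_mutated_genes)

    groups = {d: i // 2 for i, d in enumerate(drugs)}

    # --- subtype and center labels
    subtype_labels = pd.Series(
        rng.choice(subtype_names, size=spec.n_patients), index=patients, name="subtype"
    )
    centers = pd.Series(
        [f"c{i + 1}" for i in rng.integers(0, spec.n_centers, size=spec.n_patients)],
        index=patients,
        name="center",
    )

    # --- expression: baseline + subtype mean shift + unit noise, floored at 0
    mu = rng.normal(8.0, 1.0, size=spec.n_genes)
    noise = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_patients))
    L = mu[:, None] + noise
    gene_pos = {g: i for i, g in enumerate(genes)}
    for st, st_genes in subtype_genes.items():
        cols = np.flatnonzero((subtype_labels == st).to_numpy())
        rows = [gene_pos[g] for g in st_genes]
        L[np.ix_(rows, cols)] += spec.subtype_separation
    expr_values = np.maximum(L, 0.0)
    expression = ExpressionMatrix(
        pd.DataFrame(expr_values, index=genes, columns=patients)
    )

    # --- latent responses from planted genes
    def standardized(rows: list[str]) -> np.ndarray:
        block = L[[gene_pos[g] for g in rows], :]
        z = (block - block.mean(axis=1, keepdims=True)) / block.std(
            axis=1, keepdims=True, ddof=1
        )
        s = z.mean(axis=0)
        return (s - s.mean()) / s.std(ddof=1)

    factor = {g: standardized(shared_genes[g]) for g in range(n_groups)}
    a = np.sqrt(max(0.0, 1.0 - spec.cross_drug_rho - spec.noise_sd**2))
    latent = {}
    for d in drugs:
        s_d = standardized(private_genes[d])
        eps = rng.normal(0.0, 1.0, size=spec.n_patients)
        latent[d] = (
            np.sqrt(spec.cross_drug_rho) * factor[groups[d]]
            + a * s_d
            + spec.noise_sd * eps
        )
    latent_df = pd.DataFrame(latent, index=patients)

    # --- observed responses: AUC affine in latent (with a per-drug mean
    # offset, as real drug panels have); IC50 monotone in AUC
    drug_offsets = rng.normal(0.0, spec.drug_mean_sd, size=spec.n_drugs)
    rows = []
    thresholds = {}
    screened = rng.random((spec.n_patients, spec.n_drugs)) >= spec.missing_screen_fraction
    for j, d in enumerate(drugs):
        y = latent_df[d].to_numpy()
        auc = AUC_CENTER + drug_offsets[j] + AUC_SCALE * y
        ic50_raw = (
            spec.ic50_intercept
            + spec.ic50_slope * y
            + rng.normal(0.0, spec.ic50_noise_sd, size=spec.n_patients)
        )
        if spec.ic50_ceiling_fraction > 0:
            cut = np.quantile(ic50_raw, 1.0 - spec.ic50_ceiling_fraction)
            ic50_raw = np.where(ic50_raw >= cut, 10.0, ic50_raw)
        ic50 = np.clip(ic50_raw, 0.0, 10.0)
        # E[IC50] = 1 at y* = (1 - intercept)/slope; map back to AUC scale
        thresholds[d] = float(
            AUC_CENTER
            + drug_offsets[j]
            + AUC_SCALE * (1.0 - spec.ic50_intercept) / spec.ic50_slope
        )
        for i, p in enumerate(patients):
            if screened[i, j]:
                rows.append((p, d, "AUC", float(auc[i])))
                rows.append((p, d, "IC50", float(ic50[i])))
    responses = DrugResponseTable(
        pd.DataFrame(rows, columns=["sample", "drug", "metric", "value"])
    )

    # --- mutations (recurrent by construction)
    freq = rng.uniform(0.05, 0.25, size=spec.n_mutated_genes)
    calls = (rng.random((spec.n_patients, spec.n_mutated_genes)) < freq).astype(int)
    for j in range(spec.n_mutated_genes):
        while calls[:, j].sum() < 2:
            calls[rng.integers(0, spec.n_patients), j] = 1
    mutations = MutationProfile(
        pd.DataFrame(calls, index=patients, columns=mutated_genes)
    )

    # --- drug targets: both drugs of a group target the group's first genes
    n_targets = min(2, spec.signal_genes_per_drug)
    targets = {d: shared_genes[groups[d]][:n_targets] for d in drugs}
    target_map = DrugTargetMap(targets)

    # --- functional network: target genes wired to their group's signal
    # genes, over a sparse random background
    edges: list[tuple[str, str]] = []
    for g in range(n_groups):
        hub_genes = shared_genes[g][:n_targets]
        wired = shared_genes[g] + [
            pg for d in drugs if groups[d] == g for pg in private_genes[d]
        ]
        for hub in hub_genes:
            for other in wired:
                if other != hub:
                    edges.append((hub, other))
    pool = [g for block in subtype_genes.values() for g in block]
    pool += mutated_genes + genes[cursor: cursor + 50]
    pool = list(dict.fromkeys(pool))
    n_background = 2 * len(pool)
    for _ in range(n_background):
        u, v = rng.choice(len(pool), size=2, replace=False)
        edges.append((pool[u], pool[v]))
    network = network_from_edges(edges)

    # --- gene sets
    subtype_sets = GeneSetCollection(dict(subtype_genes))
    pathway_sets = {}
    for i in range(4):
        members = list(
            rng.choice(mutated_genes, size=2, replace=False)
        ) + list(rng.choice(genes[: cursor], size=4, replace=False))
        pathway_sets[f"PW{i + 1}"] = list(dict.fromkeys(members))
    pathway_sets = GeneSetCollection(pathway_sets)
    aml_relevant = sorted(
        rng.choice(genes, size=min(15, spec.n_genes), replace=False).tolist()
    )

    truth = GroundTruth(
        signal_genes={d: shared_genes[groups[d]] + private_genes[d] for d in drugs},
        shared_genes=shared_genes,
        groups=groups,
        latent=latent_df,
        thresholds=thresholds,
        subtype_genes=subtype_genes,
    )
    return SyntheticCohort(
        expression=expression,
        mutations=mutations,
        responses=responses,
        subtype_labels=subtype_labels,
        centers=centers,
        subtype_sets=subtype_sets,
        pathway_sets=pathway_sets,
        aml_relevant_genes=aml_relevant,
        drug_targets=target_map,
        network=network,
        truth=truth,
    )


def generate_planted_nea_instance(
    n_nodes: int = 60,
    background_p: float = 0.1,
    block_excess: int = 0,
    seed: int = 0,
    set_size: int = 8,
) -> tuple[FunctionalNetwork, set, set, int]:
    """Erdos-Renyi background plus ``block_excess`` extra A-F edges.

    A and F are disjoint node sets; the planted excess makes the expected
    cross-link count exceed the degree-matched null by roughly
    ``block_excess`` links.
    """
    if block_excess < 0:
        raise ValueError("block_excess must be >= 0")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < background_p:
                edges.append((nodes[i], nodes[j]))
    perm = rng.permutation(n_nodes)
    A = {nodes[i] for i in perm[:set_size]}
    F = {nodes[i] for i in perm[set_size: 2 * set_size]}
    existing = {(min(u, v), max(u, v)) for u, v in edges}
    candidates = [
        (min(u, v), max(u, v))
        for u in sorted(A)
        for v in sorted(F)
        if (min(u, v), max(u, v)) not in existing
    ]
    if block_excess > len(candidates):
        raise ValueError(
            f"block_excess={block_excess} exceeds remaining A-F capacity "
            f"({len(candidates)})"
        )
    picked = rng.choice(len(candidates), size=block_excess, replace=False)
    edges.extend(candidates[i] for i in picked)
    return network_from_edges(edges), A, F, block_excess
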