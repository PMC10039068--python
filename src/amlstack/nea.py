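"""Network enrichment analysis between gene sets.

The enrichment statistic for gene sets A and F on a functional network
is z = (d_AF - mean) / sd, where d_AF is the number of network edges
with one endpoint in A and the other in F, and the null mean/sd are
estimated over degree-preserving randomizations of the network.

The randomizer is a uniform double-edge-swap MCMC: two distinct edges
are drawn uniformly, one of the two possible rewirings is chosen at
random, and the move is rejected if it would create a self-loop or a
duplicate edge.  This symmetric-proposal chain samples (asymptotically)
uniformly from the simple graphs with the observed degree sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import spearman_safe
from .io import (
    AmlstackError,
    DrugResponseTable,
    DrugTargetMap,
    FunctionalNetwork,
    GeneSetCollection,
)

logger = logging.getLogger("amlstack")

Z_CUTOFF = 1.96
DEFAULT_N_PERM = 1000
#: swap attempts per randomization, as a multiple of the edge count
SWAPS_PER_EDGE = 10


@dataclass
class NeaResult:
    geneset_A: str
    geneset_F: str
    d_AF: int
    d_bar_AF: float
    sigma_AF: float
    z: float
    n_permutations: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.z) and self.z > Z_CUTOFF)


# ---------------------------------------------------------------------------
# Cross-link counting
# ---------------------------------------------------------------------------


def count_cross_links(A, F, network: FunctionalNetwork) -> int:
    """Edges with one endpoint in A and the other in F.

    An edge whose two endpoints each lie in both sets counts once.
    Genes absent from the network contribute no edges.
    """
    A, F = set(A), set(F)
    if not A or not F:
        raise ValueError("gene sets must be non-empty")
    count = 0
    for u, v in network.graph.edges:
        if (u in A and v in F) or (u in F and v in A):
            count += 1
    return count


def _index_network(network: FunctionalNetwork):
    nodes = list(network.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edges = np.array(
        [(idx[u], idx[v]) for u, v in network.graph.edges], dtype=np.int64
    )
    return nodes, idx, edges


def _set_mask(genes, idx, n_nodes) -> np.ndarray:
    mask = np.zeros(n_nodes, dtype=bool)
    for g in genes:
        if g in idx:
            mask[idx[g]] = True
    return mask


def _counts_for_edges(edges: np.ndarray, A_masks: np.ndarray, F_masks: np.ndarray) -> np.ndarray:
    """Cross-link counts of each (A, F) pair against one edge array.

    A_masks/F_masks: (n_pairs, n_nodes) boolean."""
    u, v = edges[:, 0], edges[:, 1]
    hits = (A_masks[:, u] & F_masks[:, v]) | (A_masks[:, v] & F_masks[:, u])
    return hits.sum(axis=1)


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------


def _rewire(edges: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniform double-edge-swap randomization of an edge array."""
    m = len(edges)
    out = edges.copy()
    present = {(min(u, v), max(u, v)) for u, v in out}
    n_attempts = SWAPS_PER_EDGE * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    orients = rng.integers(0, 2, size=n_attempts)
    for (i, j), o in zip(picks, orients):
        if i == j:
            continue
        a, b = out[i]
        c, d = out[j]
        if o:
            c, d = d, c
        # proposed edges: (a, c), (b, d)
        if a == c or b == d:
            continue
        e1 = (min(a, c), max(a, c))
        e2 = (min(b, d), max(b, d))
        if e1 == e2 or e1 in present or e2 in present:
            continue
        present.discard((min(out[i][0], out[i][1]), max(out[i][0], out[i][1])))
        present.discard((min(out[j][0], out[j][1]), max(out[j][0], out[j][1])))
        present.add(e1)
        present.add(e2)
        out[i] = e1
        out[j] = e2
    return out


def null_count_matrix(
    network: FunctionalNetwork,
    pairs: list[tuple[set, set]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> np.ndarray:
    """(n_pairs, n_perm) cross-link counts over one randomized ensemble.

    All pairs share the same n_perm degree-preserving randomizations, so
    large batches (e.g. every subtype x drug combination) cost one
    rewiring pass instead of one per pair.
    """
    nodes, idx, edges = _index_network(network)
    if len(edges) < 2:
        raise AmlstackError("network too small to rewire (< 2 edges)")
    n_nodes = len(nodes)
    A_masks = np.stack([_set_mask(A, idx, n_nodes) for A, _ in pairs])
    F_masks = np.stack([_set_mask(F, idx, n_nodes) for _, F in pairs])
    rng = np.random.default_rng(seed)
    counts = np.empty((len(pairs), n_perm), dtype=np.int64)
    for p in range(n_perm):
        rewired = _rewire(edges, rng)
        counts[:, p] = _counts_for_edges(rewired, A_masks, F_masks)
    return counts


def null_moments(
    A, F, network: FunctionalNetwork, n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> tuple[float, float]:
    """Mean and sd of the cross-link count under the degree-preserving null."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    counts = null_count_matrix(network, [(set(A), set(F))], n_perm, seed)[0]
    return float(counts.mean()), float(counts.std(ddof=1))


def nea_zscore(
    A,
    F,
    network: FunctionalNetwork,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    name_A: str = "A",
    name_F: str = "F",
) -> NeaResult:
    """Assemble the enrichment z-score for one pair of gene sets."""
    A, F = set(A), set(F)
    if not A or not F:
        raise ValueError("gene sets must be non-empty")
    d = count_cross_links(A, F, network)
    mean, sd = null_moments(A, F, network, n_perm, seed)
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (d - mean) / sd
    if degenerate:
        logger.warning(
            "NEA null for (%s, %s) is degenerate (sd = 0); z undefined", name_A, name_F
        )
    return NeaResult(
        geneset_A=name_A,
        geneset_F=name_F,
        d_AF=d,
        d_bar_AF=mean,
        sigma_AF=sd,
        z=z,
        n_permutations=n_perm,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Subtype x drug association table
# ---------------------------------------------------------------------------


def subtype_drug_table(
    subtype_sets: GeneSetCollection,
    drug_targets: DrugTargetMap,
    network: FunctionalNetwork,
    responses: DrugResponseTable,
    subtype_labels: pd.Series,
    top_k: int = 25,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    metric: str = "AUC",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrichment z and median response for every (subtype, drug) pair.

    Subtype gene sets are truncated to their top ``top_k`` genes.  Returns
    the association table and, per drug, the Spearman correlation between
    z and the median response across subtypes (negative correlation means
    stronger network interaction goes with better drug response).
    """
    sets = subtype_sets.top(top_k)
    wide = responses.pivot(metric)
    labels = subtype_labels.dropna()
    subtypes = []
    for name in sets.names():
        patients = labels.index[labels == name]
        if len(patients) == 0:
            logger.warning("subtype %s has no labelled patients; excluded", name)
            continue
        subtypes.append(name)

    drugs = sorted(drug_targets.drugs())
    pairs, keys = [], []
    for name in subtypes:
        A = set(sets[name])
        for drug in drugs:
            F = set(drug_targets.get(drug))
            if F:
                pairs.append((A, F))
                keys.append((name, drug))
    null = (
        null_count_matrix(network, pairs, n_perm, seed) if pairs else np.empty((0, 0))
    )
    null_stats = {
        key: (null[i].mean(), null[i].std(ddof=1)) for i, key in enumerate(keys)
    }

    rows = []
    for name in subtypes:
        patients = [s for s in labels.index[labels == name] if s in wide.index]
        A = set(sets[name])
        for drug in drugs:
            med = (
                float(wide.loc[patients, drug].median())
                if drug in wide.columns and patients
                else float("nan")
            )
            F = set(drug_targets.get(drug))
            if not F:
                rows.append((name, drug, float("nan"), med, False, True))
                continue
            d = count_cross_links(A, F, network)
            mean, sd = null_stats[(name, drug)]
            if sd == 0:
                rows.append((name, drug, float("nan"), med, False, True))
                continue
            z = (d - mean) / sd
            rows.append((name, drug, z, med, z > Z_CUTOFF, False))
    table = pd.DataFrame(
        rows,
        columns=["subtype", "drug", "z", "median_response", "significant", "degenerate"],
    )

    rho_rows = []
    for drug in drugs:
        sub = table[(table["drug"] == drug) & table["z"].notna() & table["median_response"].notna()]
        if len(sub) >= 3:
            rho = spearman_safe(sub["z"].to_numpy(), sub["median_response"].to_numpy())
            rho_rows.append((drug, rho, len(sub)))
    rho_df = pd.DataFrame(rho_rows, columns=["drug", "spearman_z_vs_response", "n_subtypes"])
    return table, rho_df
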