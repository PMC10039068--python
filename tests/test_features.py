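"""Feature construction: normalization, gene selections, PAS, redundancy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amlstack import (
    CohortInputs,
    ExpressionMatrix,
    FeatureMatrix,
    FeatureSpec,
    GeneSetCollection,
    assemble_features,
    compute_pas,
    drug_context_genes,
    normalize_expression,
    redundancy_filter,
    select_correlated_genes,
    select_high_variance_genes,
    select_subtype_genes,
)
from amlstack.features import spearman_safe
from amlstack.io import (
    DegenerateSampleError,
    DrugTargetMap,
    InsufficientDataError,
    network_from_edges,
)
from scipy import stats


def _expr(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestNormalize:
    def test_simple_column(self):
        em = normalize_expression(_expr([[1], [2], [3]]))
        assert em.values[:, 0].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_sample_names_offender(self):
        with pytest.raises(DegenerateSampleError, match="s0"):
            normalize_expression(_expr([[5], [5], [5]]))

    def test_postcondition_median_zero_sd_one(self, rng):
        em = normalize_expression(_expr(rng.gamma(2, 2, size=(31, 8))))
        med = np.median(em.values, axis=0)
        sd = em.values.std(axis=0, ddof=1)
        assert np.allclose(med, 0, atol=1e-12)
        assert np.allclose(sd, 1, atol=1e-9)

    def test_idempotent_for_odd_sample_count(self, rng):
        em = normalize_expression(_expr(rng.normal(size=(25, 6))))
        twice = normalize_expression(em)
        assert np.abs(twice.values - em.values).max() < 1e-9

    def test_per_gene_option(self, rng):
        em = normalize_expression(_expr(rng.normal(size=(5, 21))), per_gene=True)
        assert np.allclose(np.median(em.values, axis=1), 0, atol=1e-12)


class TestSubtypeGenes:
    @pytest.mark.parametrize(
        "sets,k,expected",
        [
            ({"A": ["g1", "g2"], "B": ["g2", "g3"]}, 2, ["g1", "g2", "g3"]),
            ({"A": ["g1", "g2"], "B": ["g3"]}, 99, ["g1", "g2", "g3"]),
            ({"A": ["g1", "g2", "g3"]}, 1, ["g1"]),
        ],
    )
    def test_union_dedup_truncation(self, sets, k, expected):
        assert select_subtype_genes(GeneSetCollection(sets), k) == expected

    def test_eleven_sets_topk_bound(self):
        sets = {f"S{i}": [f"s{i}g{j}" for j in range(30)] for i in range(11)}
        genes = select_subtype_genes(GeneSetCollection(sets), 15)
        assert len(genes) <= 165


class TestPas:
    def test_mean_of_members(self):
        em = _expr([[1.0], [-1.0]], genes=["g1", "g2"])
        fm = compute_pas(em, GeneSetCollection({"P": ["g1", "g2"]}), ["g1"])
        assert fm.values.loc["s0", "PAS:P"] == 0.0

    def test_single_measured_gene(self):
        em = _expr([[2.5]], genes=["g1"])
        fm = compute_pas(em, GeneSetCollection({"P": ["g1", "gX"]}), ["g1"])
        assert fm.values.loc["s0", "PAS:P"] == 2.5

    def test_pathway_without_mutated_gene_skipped(self):
        em = _expr([[1.0]], genes=["g1"])
        fm = compute_pas(em, GeneSetCollection({"P": ["g1"]}), ["other"])
        assert fm.values.shape[1] == 0

    def test_sum_mode(self):
        em = _expr([[1.0], [2.0]], genes=["g1", "g2"])
        fm = compute_pas(em, GeneSetCollection({"P": ["g1", "g2"]}), ["g1"], mode="sum")
        assert fm.values.loc["s0", "PAS:P"] == 3.0

    def test_matches_direct_mean_oracle(self, rng):
        em = _expr(rng.normal(size=(10, 6)))
        genes = ["g1", "g4", "g7"]
        fm = compute_pas(em, GeneSetCollection({"P": genes}), ["g1"])
        expected = em.data.loc[genes].mean(axis=0)
        assert np.allclose(fm.values["PAS:P"], expected)


def test_default_aml_relevant_list_loads():
    from amlstack import default_aml_relevant_genes

    genes = default_aml_relevant_genes()
    assert "FLT3" in genes and "BCL2" in genes
    assert len(genes) == len(set(genes))


class TestDrugContext:
    def test_one_hop_neighbourhood(self, path_network):
        tm = DrugTargetMap({"d": ["b"]})
        assert drug_context_genes("d", tm, path_network) == ["b", "a", "c", "f"]

    def test_target_not_in_network(self, path_network):
        tm = DrugTargetMap({"d": ["zzz"]})
        assert drug_context_genes("d", tm, path_network) == ["zzz"]

    def test_no_targets(self, path_network):
        assert drug_context_genes("d", DrugTargetMap({"d": []}), path_network) == []


class TestHighVariance:
    def test_ranking(self):
        em = _expr([[0, 4], [0, 2], [1, 1]], genes=["g1", "g2", "g3"])
        assert select_high_variance_genes(em, 2) == ["g1", "g2"]

    def test_tie_broken_lexicographically(self):
        em = _expr([[0, 2], [0, 2], [0, 0]], genes=["gb", "ga", "gc"])
        assert select_high_variance_genes(em, 1) == ["ga"]

    def test_k_exceeding_gene_count_warns(self, caplog):
        em = _expr([[0, 1], [1, 0]])
        assert len(select_high_variance_genes(em, 10)) == 2
        assert "only" in caplog.text


class TestCorrelatedGenes:
    def test_perfect_gene_always_selected(self, rng):
        X = rng.normal(size=(20, 9))
        em = _expr(X)
        response = pd.Series(X[3], index=em.samples)
        assert "g3" in select_correlated_genes(em, response, 1)

    def test_constant_gene_ranks_last(self, rng):
        X = rng.normal(size=(4, 8))
        X[2] = 7.0
        em = _expr(X)
        response = pd.Series(rng.normal(size=8), index=em.samples)
        assert select_correlated_genes(em, response, 4)[-1] == "g2"

    def test_too_few_overlapping_samples(self):
        em = _expr([[1, 2, 3]], genes=["g1"])
        response = pd.Series([1.0, 2.0], index=["s0", "s1"])
        with pytest.raises(InsufficientDataError):
            select_correlated_genes(em, response, 1)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        em = _expr(rng.normal(size=(12, 10)))
        y = pd.Series(rng.normal(size=10), index=em.samples)
        base = select_correlated_genes(em, y, 5)
        warped = select_correlated_genes(em, np.exp(y * 0.5) + 3, 5)
        assert base == warped

    def test_recovers_planted_generative_genes(self, small_cohort):
        ci = small_cohort.cohort_inputs()
        wide = small_cohort.responses.pivot("AUC")
        drug = small_cohort.responses.drugs[0]
        picked = select_correlated_genes(ci.expr_norm, wide[drug], 100)
        planted = set(small_cohort.truth.signal_genes[drug])
        assert len(planted & set(picked)) / len(planted) >= 0.8


# frozen vectors: rho(f1,f2)=0.942, rho(f2,f3)=0.926, rho(f1,f3)=0.872
CHAIN_F1 = [2.305, 1.299, -2.315, 1.217, -0.643, -0.035, 0.009, -0.212, -1.49, 0.647, -0.242, 1.729, 0.208, -1.02, -0.498, 0.697, 0.817, -0.369, -3.211, 0.802, 0.336, -0.958, -0.476, 0.867, 2.43, -0.857, 0.7, 0.609, 0.022, -0.721]
CHAIN_F2 = [1.378, 1.667, -2.806, 0.955, -0.846, 0.561, -0.267, -0.262, -1.218, 1.343, -0.369, 2.374, 0.664, -1.1, -0.149, 0.418, 1.272, -0.557, -3.496, 1.247, 0.724, -1.341, -0.014, 0.584, 2.695, -0.88, 0.549, 0.333, 0.286, -0.319]
CHAIN_F3 = [1.344, 1.959, -3.708, 1.282, -1.5, 0.555, -0.906, -0.27, -1.006, 2.55, 0.282, 1.449, -0.064, -1.821, -0.742, 0.932, 0.723, -1.456, -2.559, 1.747, 1.841, -1.318, -0.045, 1.176, 3.124, -1.833, 0.088, -0.578, -0.315, -0.53]


class TestRedundancyFilter:
    def _fm(self, cols: dict) -> FeatureMatrix:
        df = pd.DataFrame(cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))])
        return FeatureMatrix(df, {c: "high_variance" for c in df.columns})

    def test_identical_feature_dropped(self):
        fm = self._fm({"f1": [1, 2, 3, 4], "f2": [1, 2, 3, 4]})
        assert redundancy_filter(fm, 0.90).features == ["f1"]

    def test_uncorrelated_all_retained(self):
        fm = self._fm({"f1": [1, 2, 3, 4], "f2": [1, -1, 1, -1]})
        assert redundancy_filter(fm, 0.90).features == ["f1", "f2"]

    def test_chain_keeps_ends(self):
        # greedy: f1 kept; f2 dropped (|rho| with f1 > 0.9); f3 kept
        # because its correlation with the retained f1 is below the cutoff
        fm = self._fm({"f1": CHAIN_F1, "f2": CHAIN_F2, "f3": CHAIN_F3})
        r12 = stats.spearmanr(CHAIN_F1, CHAIN_F2).statistic
        r23 = stats.spearmanr(CHAIN_F2, CHAIN_F3).statistic
        r13 = stats.spearmanr(CHAIN_F1, CHAIN_F3).statistic
        assert r12 > 0.9 and r23 > 0.9 and r13 <= 0.9
        assert redundancy_filter(fm, 0.90).features == ["f1", "f3"]

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=15, deadline=None)
    def test_output_never_violates_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(12, 4))
        mix = base @ rng.normal(size=(4, 10)) + 0.3 * rng.normal(size=(12, 10))
        fm = self._fm({f"f{j}": mix[:, j] for j in range(10)})
        out = redundancy_filter(fm, 0.90)
        vals = out.values.to_numpy()
        for i in range(vals.shape[1]):
            for j in range(i + 1, vals.shape[1]):
                assert abs(spearman_safe(vals[:, i], vals[:, j])) <= 0.90 + 1e-12


class TestAssemble:
    def test_single_source_bounded(self, small_cohort):
        ci = small_cohort.cohort_inputs()
        spec = FeatureSpec(variance_top_k=10, feature_sources=("high_variance",))
        fm = assemble_features(ci, spec)
        assert 1 <= len(fm.features) <= 10
        assert set(fm.provenance.values()) == {"high_variance"}

    def test_dedup_keeps_first_source_provenance(self):
        rng = np.random.default_rng(5)
        em = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(4, 8)),
                index=["gA", "gB", "gC", "gD"],
                columns=[f"s{i}" for i in range(8)],
            )
        )
        ci = CohortInputs(
            expr_norm=em,
            subtype_sets=GeneSetCollection({"S": ["gA", "gB"]}),
            aml_relevant_genes=["gB", "gC"],
        )
        spec = FeatureSpec(feature_sources=("subtype", "aml_relevant"))
        fm = assemble_features(ci, spec)
        assert fm.provenance["gB"] == "subtype"
        assert fm.provenance["gC"] == "aml_relevant"

    def test_deterministic_feature_lists(self, small_cohort, small_spec):
        ci = small_cohort.cohort_inputs()
        drug = small_cohort.responses.drugs[0]
        wide = small_cohort.responses.pivot("AUC")
        a = assemble_features(ci, small_spec, drug, wide[drug])
        b = assemble_features(ci, small_spec, drug, wide[drug])
        assert a.features == b.features
        assert a.provenance == b.provenance
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_count_matches_independent_recount(self, small_cohort):
        """Brute-force oracle: union of enabled sources, deduplicated, then
        greedily filtered, recomputed independently of assemble_features."""
        ci = small_cohort.cohort_inputs()
        spec = FeatureSpec(
            variance_top_k=30,
            feature_sources=("subtype", "mutated", "high_variance"),
        )
        fm = assemble_features(ci, spec)

        union: dict[str, str] = {}
        for g in select_subtype_genes(ci.subtype_sets, spec.subtype_top_k):
            union.setdefault(g, "subtype")
        for g in ci.mutations.mutated_genes():
            union.setdefault(g, "mutated")
        for g in select_high_variance_genes(ci.expr_norm, 30):
            union.setdefault(g, "high_variance")
        order = {"subtype": 0, "mutated": 3, "high_variance": 5}
        cols = sorted(union, key=lambda g: (order[union[g]], g))
        X = ci.expr_norm.data.loc[cols].T.to_numpy()
        keep = []
        for j in range(X.shape[1]):
            if all(abs(spearman_safe(X[:, j], X[:, i])) <= 0.90 for i in keep):
                keep.append(j)
        assert fm.features == [cols[j] for j in keep]
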