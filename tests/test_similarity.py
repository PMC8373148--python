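"""Pathway-disease similarity statistics, standardisation and ORA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from disconet import (
    CoexpressionNetwork,
    PathwayCollection,
    pathway_similarity,
    interactome_similarity,
    similarity_matrix,
    standardize_rows,
    fisher_ora,
    adjust_by,
    enrich,
)
from disconet.similarity import SimilarityMatrix
from conftest import random_network, random_knowledge_graph


def brute_pathway_sim(proteins, network):
    pairs = list(combinations(sorted(set(proteins)), 2))
    hits = sum(1 for p in pairs if p in network.edge_set)
    return hits / len(pairs)


def brute_interactome_sim(proteins, network, kg):
    proteins = set(proteins)
    supported = {e for e in kg.edge_set()
                 if e[0] in proteins and e[1] in proteins}
    if not supported:
        return None
    return sum(1 for e in supported if e in network.edge_set) / len(supported)


def hypergeom_tail(overlap, n_universe, n_pathway, n_query):
    """Direct tail summation of the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(n_pathway, n_query) + 1):
        total += (comb(n_pathway, k) * comb(n_universe - n_pathway,
                                            n_query - k)
                  / comb(n_universe, n_query))
    return total


class TestPairwiseSimilarity:
    def test_saturated_pathway(self):
        network = CoexpressionNetwork("d", 5, {
            ("A", "B"): 0.9, ("A", "C"): 0.8, ("B", "C"): 0.7})
        assert pathway_similarity({"A", "B", "C"}, network) == 1.0

    def test_disjoint_pathway_scores_zero(self):
        network = CoexpressionNetwork("d", 5, {("A", "B"): 0.9})
        assert pathway_similarity({"X", "Y", "Z"}, network) == 0.0

    def test_denominator_counts_all_pathway_pairs(self):
        # only 1 of C(5,2)=10 pairs present, even though 3 of 5
        # proteins never made it into the network
        network = CoexpressionNetwork("d", 9, {("A", "B"): 0.9})
        value = pathway_similarity({"A", "B", "C", "D", "E"}, network)
        assert value == pytest.approx(1 / 10)

    def test_pathway_sim_matches_enumeration_oracle(self, rng):
        proteins = [f"P{i}" for i in range(5)]
        network = random_network(rng, [f"P{i}" for i in range(9)], 12)
        assert pathway_similarity(proteins, network) == \
            pytest.approx(brute_pathway_sim(proteins, network))

    def test_small_pathway_rejected(self):
        network = CoexpressionNetwork("d", 3, {})
        with pytest.raises(ValueError):
            pathway_similarity({"A"}, network)

    def test_interactome_sim_saturation_zero_and_missing(self, rng):
        kg = random_knowledge_graph(rng, ["A", "B", "C"], 3)
        full = CoexpressionNetwork("d", 3, {
            ("A", "B"): 0.9, ("A", "C"): 0.8, ("B", "C"): 0.7})
        empty = CoexpressionNetwork("d", 3, {})
        assert interactome_similarity({"A", "B", "C"}, full, kg) == 1.0
        assert interactome_similarity({"A", "B", "C"}, empty, kg) == 0.0
        assert interactome_similarity({"X", "Y"}, full, kg) is None

    def test_interactome_sim_matches_induced_subgraph_oracle(self, rng):
        proteins = [f"P{i}" for i in range(12)]
        for trial in range(20):
            local = np.random.default_rng(trial)
            kg = random_knowledge_graph(local, proteins, 18)
            network = random_network(local, proteins, 20)
            pathway = set(local.choice(proteins, size=6, replace=False))
            got = interactome_similarity(pathway, network, kg)
            expected = brute_interactome_sim(pathway, network, kg)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)

    def test_relabeling_equivariance(self, rng):
        proteins = [f"P{i}" for i in range(8)]
        network = random_network(rng, proteins, 10)
        pathway = set(proteins[:5])
        mapping = {p: f"Q{i:02d}" for i, p in enumerate(reversed(proteins))}
        renamed = CoexpressionNetwork(
            "d", network.universe_size,
            {tuple(sorted((mapping[a], mapping[b]))): w
             for (a, b), w in network.edges.items()})
        assert pathway_similarity(pathway, network) == pytest.approx(
            pathway_similarity({mapping[p] for p in pathway}, renamed))

    def test_pathway_sim_monotone_in_network_edges(self, rng):
        proteins = [f"P{i}" for i in range(6)]
        network = random_network(rng, proteins, 5)
        pathway = set(proteins[:4])
        before = pathway_similarity(pathway, network)
        extra = dict(network.edges)
        new_pair = next(p for p in combinations(sorted(proteins), 2)
                        if p not in extra)
        extra[new_pair] = 0.5
        after = pathway_similarity(
            pathway, CoexpressionNetwork("d", 6, extra))
        assert after >= before


class TestSimilarityMatrix:
    def test_single_cell_matrix(self, rng):
        network = random_network(rng, ["A", "B", "C"], 2)
        pw = PathwayCollection({"PW": frozenset({"A", "B", "C"})})
        matrix = similarity_matrix(pw, {"d": network}, "pathway")
        assert matrix.raw.shape == (1, 1)

    def test_interactome_method_requires_knowledge(self, rng, tiny_pathways):
        network = random_network(rng, ["A", "B"], 1)
        with pytest.raises(ValueError):
            similarity_matrix(tiny_pathways, {"d": network}, "interactome")

    def test_interactome_sim_at_least_pathway_sim_on_subset_fixture(self, rng):
        """When the network's pathway pairs all lie in the interactome,
        restricting the denominator can only raise the score."""
        proteins = [f"P{i}" for i in range(8)]
        kg = random_knowledge_graph(rng, proteins, 20)
        supported = sorted(kg.edge_set())
        chosen = [supported[i] for i in
                  rng.choice(len(supported), size=6, replace=False)]
        network = CoexpressionNetwork(
            "d", 8, {pair: 0.9 for pair in chosen})
        pw = PathwayCollection({"PW": frozenset(proteins)})
        m1 = similarity_matrix(pw, {"d": network}, "pathway")
        m2 = similarity_matrix(pw, {"d": network}, "interactome", knowledge=kg)
        assert m2.raw.iloc[0, 0] >= m1.raw.iloc[0, 0]

    def test_planted_module_scores_its_disease_highest(self, small_cohort):
        from disconet.preprocess import preprocess_cohort
        from disconet import build_disease_networks, generate_pathways
        study, truth = small_cohort
        processed, _ = preprocess_cohort(study)
        nets = build_disease_networks(processed, fraction=0.01)
        disease_nets = {k: v for k, v in nets.items() if k != "normal"}
        pw = generate_pathways(study.gene_ids, 2, (10, 14), 1.0, seed=0,
                               modules=truth.module_genes)
        matrix = similarity_matrix(pw, disease_nets, "pathway")
        for i, pid in enumerate(pw):
            mod = sorted(truth.module_genes)[i % len(truth.module_genes)]
            target = truth.module_disease[mod]
            row = matrix.raw.loc[pid]
            others = row.drop(target)
            assert row[target] > others.max()


class TestStandardizeRows:
    def test_linear_row(self):
        raw = pd.DataFrame([[0.2, 0.4, 0.6]], index=["p"],
                           columns=["a", "b", "c"])
        out = standardize_rows(SimilarityMatrix(raw, raw.copy(), "pathway"))
        assert np.allclose(out.standardized.loc["p"], [0.0, 0.5, 1.0])

    def test_constant_row_maps_to_zero(self):
        raw = pd.DataFrame([[0.3, 0.3]], index=["p"], columns=["a", "b"])
        out = standardize_rows(SimilarityMatrix(raw, raw.copy(), "pathway"))
        assert (out.standardized.loc["p"] == 0.0).all()

    def test_nonconstant_rows_attain_zero_and_one(self, rng):
        raw = pd.DataFrame(rng.uniform(size=(6, 5)))
        out = standardize_rows(SimilarityMatrix(raw, raw.copy(), "pathway"))
        for _, row in out.standardized.iterrows():
            assert row.min() == 0.0 and row.max() == 1.0

    def test_missing_entries_stay_missing(self):
        raw = pd.DataFrame([[0.1, np.nan, 0.5]], index=["p"],
                           columns=list("abc"))
        out = standardize_rows(SimilarityMatrix(raw, raw.copy(), "pathway"))
        row = out.standardized.loc["p"]
        assert np.isnan(row["b"])
        assert row["a"] == 0.0 and row["c"] == 1.0


class TestFisherAndBY:
    def test_query_equals_universe_gives_p_one(self):
        u = {f"g{i}" for i in range(20)}
        assert fisher_ora(u, u, u) == pytest.approx(1.0)

    def test_full_overlap_small_universe(self):
        universe = [f"g{i}" for i in range(20)]
        pathway = set(universe[:5])
        assert fisher_ora(pathway, pathway, universe) == \
            pytest.approx(1 / comb(20, 5))

    def test_random_tables_match_tail_summation(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(40)]
        for _ in range(50):
            n_p = int(rng.integers(2, 20))
            n_q = int(rng.integers(2, 20))
            pathway = set(rng.choice(universe, size=n_p, replace=False))
            query = set(rng.choice(universe, size=n_q, replace=False))
            got = fisher_ora(query, pathway, universe)
            expected = hypergeom_tail(len(query & pathway), 40, n_p, n_q)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_by_single_p_and_hand_evaluated_m2(self):
        assert adjust_by([0.2])[0] == pytest.approx(0.2)
        # m=2, c(2)=1.5; step-up: p2' = min(1, .5*1.5) = .75,
        # p1' = min(.75, .01*2*1.5/1) = .03
        adj = adjust_by([0.01, 0.5])
        assert adj[0] == pytest.approx(0.03)
        assert adj[1] == pytest.approx(0.75)

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_by_matches_hand_step_up_small_m(self, m, rng):
        p = np.sort(rng.uniform(size=m))
        c_m = sum(1 / i for i in range(1, m + 1))
        expected = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            prev = min(prev, p[rank - 1] * m * c_m / rank)
            expected[rank - 1] = prev
        assert np.allclose(adjust_by(p), expected, atol=1e-12)

    def test_by_dominates_bh(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=30)
        by = adjust_by(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert (by >= bh - 1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_by([0.5, 1.2])


class TestEnrich:
    def test_query_outside_all_pathways(self, tiny_pathways):
        universe = sorted(tiny_pathways.universe | {"x1", "x2", "x3"})
        table = enrich({"x1", "x2"}, tiny_pathways, universe)
        assert not table["significant"].any()

    def test_concentrated_query_flags_its_pathway(self, tiny_pathways):
        universe = sorted(tiny_pathways.universe | {f"bg{i}" for i in range(40)})
        table = enrich(set(tiny_pathways["PW2"]), tiny_pathways, universe)
        row = table[table["pathway"] == "PW2"].iloc[0]
        # oracle: the full pipeline by hand
        raw = [hypergeom_tail(len(set(tiny_pathways["PW2"])
                                  & set(tiny_pathways[pid])),
                              len(universe), len(tiny_pathways[pid]), 4)
               for pid in tiny_pathways]
        expected_adj = adjust_by(raw)
        for i, pid in enumerate(tiny_pathways):
            got = table[table["pathway"] == pid].iloc[0]
            assert got["adj_p"] == pytest.approx(expected_adj[i], abs=1e-10)
            assert bool(got["significant"]) == (expected_adj[i] < 0.05)
        assert row["overlap"] == 4
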