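"""Reference selection, similarity rescaling and hierarchical clustering."""

import itertools
import math

import dendropy
import numpy as np
import pytest

import ancestrymapper as am
from ancestrymapper.errors import (
    DegenerateScaleError,
    EmptyPopulationError,
    IncomparablePairError,
)
from conftest import naive_rms_distance


def make_gm(values, sample_ids=None, snp_ids=None, metadata=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return am.GenotypeMatrix(
        sample_ids or [f"S{i}" for i in range(n)],
        snp_ids or [f"snp{j}" for j in range(m)],
        values,
        metadata,
    )


class TestPairwiseDistances:
    def test_hand_computed_distance(self):
        gm = make_gm([[2, 2], [4, 4]])
        d = am.pairwise_distances(gm).to_numpy()
        # sqrt(((4-2)^2 + (4-2)^2) / 2) = 2
        assert d[0, 1] == pytest.approx(2.0)
        assert d[0, 0] == 0.0 and d[1, 1] == 0.0

    def test_identical_vectors_distance_zero(self):
        gm = make_gm([[2, 3, 4], [2, 3, 4]])
        assert am.pairwise_distances(gm).to_numpy()[0, 1] == 0.0

    def test_symmetry_and_oracle_on_random_fixture(self):
        rng = np.random.default_rng(4)
        values = rng.choice([2.0, 3.0, 4.0, np.nan], size=(8, 60),
                            p=[0.3, 0.3, 0.3, 0.1])
        gm = make_gm(values)
        d = am.pairwise_distances(gm).to_numpy()
        np.testing.assert_allclose(d, d.T)
        assert (d >= 0).all()
        for i, j in itertools.combinations(range(8), 2):
            expected, _ = naive_rms_distance(values[i], values[j])
            assert d[i, j] == pytest.approx(expected)

    def test_incomparable_pair_named(self):
        values = np.array([[2.0, np.nan], [np.nan, 4.0], [2.0, 2.0]])
        with pytest.raises(IncomparablePairError, match="S0.*S1"):
            am.pairwise_distances(make_gm(values))


class TestSelectReference:
    def test_smallest_median_wins(self):
        # d(A,B) = d(A,C) = h and d(B,C) = 2h -> A has the smallest median
        gm = make_gm(
            [[3, 3, 2, 2], [4, 4, 2, 2], [2, 2, 2, 2]], ["A", "B", "C"]
        )
        d = am.pairwise_distances(gm).to_numpy()
        assert d[0, 1] == pytest.approx(d[0, 2])
        assert d[1, 2] == pytest.approx(2 * d[0, 1])
        assert am.select_reference(gm, ["A", "B", "C"]) == "A"
        # invariant to member input order
        assert am.select_reference(gm, ["C", "B", "A"]) == "A"

    def test_matches_exhaustive_median_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.choice([2.0, 3.0, 4.0], size=(7, 40))
        ids = [f"M{i}" for i in range(7)]
        gm = make_gm(values, ids)
        best = None
        for i in range(7):
            dists = sorted(
                naive_rms_distance(values[i], values[j])[0]
                for j in range(7) if j != i
            )
            med = float(np.median(dists))
            mean = float(np.mean(dists))
            key = (med, mean, ids[i])
            if best is None or key < best[0]:
                best = (key, ids[i])
        assert am.select_reference(gm, ids) == best[1]

    def test_single_member_and_tie_break(self):
        gm = make_gm([[2, 2]], ["only"])
        assert am.select_reference(gm, ["only"]) == "only"
        # all pairwise distances equal -> lexicographically smallest id
        gm = make_gm([[2, 2, 4], [2, 4, 2], [4, 2, 2]], ["c", "b", "a"])
        d = am.pairwise_distances(gm).to_numpy()
        off = d[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        assert am.select_reference(gm, ["c", "b", "a"]) == "a"

    def test_empty_population(self):
        gm = make_gm([[2, 2]])
        with pytest.raises(EmptyPopulationError):
            am.select_reference(gm, [])


class TestBuildPanel:
    def test_one_entry_per_population_with_containment(self, tiny):
        panel = am.build_panel(tiny.genotypes)
        assert len(panel) == 2
        for pop, sid in zip(panel.populations, panel.sample_ids):
            assert tiny.metadata.loc[sid, "population"] == pop

    def test_panel_size_matches_population_count(self):
        # a 51-population panel yields 51 reference coordinates
        cfg = am.SimulationConfig(
            n_continents=17, pops_per_continent=3, inds_per_pop=2, n_snps=120,
            seed=9,
        )
        ds = am.simulate(cfg)
        panel = am.build_panel(ds.genotypes)
        assert len(panel) == 51

    def test_empty_population_error(self, tiny):
        import pandas as pd

        gm = tiny.genotypes
        meta = pd.concat(
            [tiny.metadata,
             pd.DataFrame({"population": ["ghost"]}, index=["nobody"])]
        )
        members = [s for s in gm.sample_ids]
        with pytest.raises(EmptyPopulationError):
            am.build_panel(gm.subset_samples(members), meta)

    def test_selected_reference_is_central(self, continental, continental_panel):
        """The reference's mean distance to co-members is at most the
        population average of that quantity."""
        gm = continental.genotypes
        for pop, ref in zip(continental_panel.populations,
                            continental_panel.sample_ids):
            members = [s for s in gm.sample_ids
                       if continental.metadata.loc[s, "population"] == pop]
            d = am.pairwise_distances(gm, members).to_numpy()
            mean_to_others = d.sum(axis=1) / (len(members) - 1)
            ref_mean = mean_to_others[members.index(ref)]
            assert ref_mean <= mean_to_others.mean() + 1e-12

    def test_panel_round_trip(self, tmp_path, tiny_panel):
        tiny_panel.to_dir(tmp_path / "panel")
        back = am.ReferencePanel.from_dir(tmp_path / "panel")
        assert back.populations == tiny_panel.populations
        assert back.sample_ids == tiny_panel.sample_ids
        np.testing.assert_array_equal(back.genotypes, tiny_panel.genotypes)


class TestSimilarityMatrix:
    def scalene_panel(self):
        # raw off-diagonals: d(a,b)=sqrt(2), d(a,c)=sqrt(3), d(b,c)=1
        genotypes = np.array(
            [[2, 2, 2, 2], [4, 4, 2, 2], [4, 4, 4, 2]], dtype=float
        )
        return am.ReferencePanel(
            ["A", "B", "C"], ["a", "b", "c"], genotypes,
            ["s1", "s2", "s3", "s4"],
        )

    def test_affine_rescale_endpoints_and_midpoint(self):
        rdm = am.reference_similarity_matrix(self.scalene_panel())
        sim = rdm.similarity_frame()
        assert sim.loc["B", "C"] == pytest.approx(100.0)   # closest pair
        assert sim.loc["A", "C"] == pytest.approx(0.0)     # farthest pair
        expected_mid = 100.0 * (math.sqrt(3) - math.sqrt(2)) / (math.sqrt(3) - 1.0)
        assert sim.loc["A", "B"] == pytest.approx(expected_mid)
        assert np.allclose(np.diag(rdm.similarity), 100.0)

    def test_similarity_inversely_monotone_with_raw(self, continental_panel):
        rdm = am.reference_similarity_matrix(continental_panel)
        off = ~np.eye(len(continental_panel), dtype=bool)
        raw, sim = rdm.raw[off], rdm.similarity[off]
        order = np.argsort(raw)
        assert (np.diff(sim[order]) <= 1e-9).all()
        assert sim.max() == pytest.approx(100.0)
        assert sim.min() == pytest.approx(0.0)

    def test_degenerate_scale(self):
        panel = am.ReferencePanel(
            ["A", "B"], ["a", "b"],
            np.array([[2.0, 2.0], [4.0, 4.0]]), ["s1", "s2"],
        )
        with pytest.raises(DegenerateScaleError):
            am.reference_similarity_matrix(panel)


class TestDendrogram:
    def test_identical_references_merge_first_at_zero(self):
        genotypes = np.array(
            [[2, 2, 2], [2, 2, 2], [4, 4, 4]], dtype=float
        )
        panel = am.ReferencePanel(["A", "B", "C"], ["a", "b", "c"],
                                  genotypes, ["s1", "s2", "s3"])
        dendro = am.cluster_references(panel)
        assert dendro.linkage[0, 2] == pytest.approx(0.0)
        assert set(dendro.linkage[0, :2].astype(int)) == {0, 1}

    def test_first_merge_is_closest_pair(self, continental_panel):
        dendro = am.cluster_references(continental_panel)
        rdm = am.reference_similarity_matrix(continental_panel)
        n = len(continental_panel)
        off = np.where(~np.eye(n, dtype=bool))
        i, j = min(zip(*off), key=lambda ij: rdm.raw[ij])
        assert set(dendro.linkage[0, :2].astype(int)) == {i, j}

    def test_four_leaf_complete_linkage_matches_brute_force(self):
        rng = np.random.default_rng(6)
        genotypes = rng.choice([2.0, 3.0, 4.0], size=(4, 30))
        panel = am.ReferencePanel(
            ["A", "B", "C", "D"], list("abcd"), genotypes,
            [f"s{j}" for j in range(30)],
        )
        dendro = am.cluster_references(panel, "complete")

        # independent naive agglomeration over active clusters
        gm = am.GenotypeMatrix(list("abcd"), panel.snp_ids, genotypes)
        d = am.pairwise_distances(gm).to_numpy()
        clusters = {i: [i] for i in range(4)}
        heights = []
        while len(clusters) > 1:
            pairs = list(itertools.combinations(sorted(clusters), 2))
            def complete(pair):
                a, b = pair
                return max(d[i, j] for i in clusters[a] for j in clusters[b])
            best = min(pairs, key=complete)
            heights.append(complete(best))
            clusters[best[0]] += clusters.pop(best[1])
        np.testing.assert_allclose(dendro.merge_heights(), heights)
        assert (np.diff(dendro.merge_heights()) >= -1e-12).all()

    def test_newick_export_parses_with_correct_leaves(self, continental_panel):
        dendro = am.cluster_references(continental_panel)
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(continental_panel.populations)
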