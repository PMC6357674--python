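"""Relationship matrix, PCA, distances and neighbor joining."""

import numpy as np
import pandas as pd
import pytest

from lineage_scope import (
    euclidean_distance,
    nj_tree,
    pc_geo_correlation,
    pca,
    relationship_matrix,
)
from lineage_scope.genotype_io import SampleRecord
from lineage_scope.structure_analysis import DistanceMatrix, random_additive_tree

_random_additive_tree = random_additive_tree

from conftest import make_matrix


class TestRelationshipMatrix:
    def test_identical_samples_share_diagonal(self):
        gm = make_matrix([[0, 2, 0, 2], [0, 2, 0, 2], [2, 0, 2, 0]])
        a = relationship_matrix(gm).matrix
        assert a[0, 1] == pytest.approx(a[0, 0])

    def test_hand_computed_oracle(self):
        calls = np.array([[0, 2, 1, 0], [2, 0, 1, 2], [0, 2, 2, 2]], dtype=np.int8)
        gm = make_matrix(calls)
        p = calls.astype(float).sum(axis=0) / 6
        w = calls - 2 * p
        expected = w @ w.T / (2 * (p * (1 - p)).sum())
        a = relationship_matrix(gm).matrix
        assert np.allclose(a, expected, atol=1e-12)

    def test_centering_makes_total_sum_near_zero(self, default_panel):
        a = relationship_matrix(default_panel["gm"]).matrix
        # W columns are centered only up to missing-data imputation noise
        assert abs(a.sum()) / np.abs(a).sum() < 0.01

    def test_monomorphic_only_errors(self):
        with pytest.raises(ValueError):
            relationship_matrix(make_matrix([[2, 2], [2, 2]]))


class TestPca:
    def test_two_block_separation(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.05, 0.95, 300)
        p2 = rng.uniform(0.05, 0.95, 300)
        block1 = (2 * (rng.random((10, 300)) < p1)).astype(np.int8)
        block2 = (2 * (rng.random((10, 300)) < p2)).astype(np.int8)
        gm = make_matrix(np.vstack([block1, block2]))
        res = pca(relationship_matrix(gm))
        pc1 = res.scores["PC1"].to_numpy()
        assert max(pc1[:10]) < min(pc1[10:]) or max(pc1[10:]) < min(pc1[:10])

    def test_spectral_reconstruction(self, default_panel):
        a = relationship_matrix(default_panel["gm"])
        res = pca(a, n_components=a.matrix.shape[0])
        v = res.eigenvectors.to_numpy()
        recon = (v * res.eigenvalues) @ v.T
        assert np.abs(recon - a.matrix).max() <= 1e-8

    def test_eigenvalues_descending_and_variance_fractions(self, default_panel):
        res = pca(relationship_matrix(default_panel["gm"]))
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert 0 < res.variance_explained.sum() <= 1 + 1e-12

    def test_asymmetric_input_rejected(self):
        from lineage_scope.structure_analysis import RelationshipMatrix

        bad = RelationshipMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            pca(bad)


class TestEuclideanDistance:
    def test_identical_samples_zero(self):
        gm = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert euclidean_distance(gm).matrix[0, 1] == 0.0

    def test_complete_data_arithmetic(self):
        gm = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert euclidean_distance(gm).matrix[0, 1] == pytest.approx(np.sqrt(12))

    def test_missing_rescaling(self):
        gm = make_matrix([[0, 0, -1], [2, 2, 2]])
        assert euclidean_distance(gm).matrix[0, 1] == pytest.approx(np.sqrt(3 / 2 * 8))

    def test_disjoint_pair_errors(self):
        gm = make_matrix([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="S001"):
            euclidean_distance(gm)

    def test_matches_r_dist_convention(self, default_panel):
        # spot-check a pair against the naive per-pair formula
        gm = default_panel["gm"].subset_samples(default_panel["gm"].samples[:5])
        d = euclidean_distance(gm).matrix
        x = gm.calls.astype(float)
        x[gm.calls == -1] = np.nan
        for i in range(5):
            for j in range(i + 1, 5):
                both = np.isfinite(x[i]) & np.isfinite(x[j])
                expected = np.sqrt(gm.n_sites / both.sum() * ((x[i, both] - x[j, both]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-10)


class TestNeighborJoining:
    def test_four_taxa_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> classic additive distances
        d = pd.DataFrame(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        t = nj_tree(DistanceMatrix(d.to_numpy(), list("ABCD")))
        assert t.splits() == {frozenset({"A", "B"})}
        recovered = t.leaf_distance_matrix().loc[list("ABCD"), list("ABCD")]
        assert np.allclose(recovered.to_numpy(), d.to_numpy(), atol=1e-10)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(d, ["A", "B", "C"]))
        lengths = {t.leaf_labels[c]: w for c, w in t.children[t.root]}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(5.0)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ["A", "B"]))

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            d, true_splits = _random_additive_tree(rng, 8)
            t = nj_tree(DistanceMatrix(d.to_numpy(), list(d.index)))
            assert t.splits() == true_splits
            rec = t.leaf_distance_matrix().loc[d.index, d.columns].to_numpy()
            assert np.allclose(rec, d.to_numpy(), atol=1e-8)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(9)
        d, _ = _random_additive_tree(rng, 7)
        t1 = nj_tree(DistanceMatrix(d.to_numpy(), list(d.index)))
        perm = list(rng.permutation(list(d.index)))
        dp = d.loc[perm, perm]
        t2 = nj_tree(DistanceMatrix(dp.to_numpy(), perm))
        assert t1.splits() == t2.splits()

    def test_agrees_with_dendropy_on_panel_distances(self, default_panel):
        dendropy = pytest.importorskip("dendropy")
        gm = default_panel["gm"].subset_samples(default_panel["gm"].samples[::6])
        d = euclidean_distance(gm)
        ours = nj_tree(d)
        pdm_csv = ["," + ",".join(d.samples)]
        for i, s in enumerate(d.samples):
            pdm_csv.append(s + "," + ",".join(f"{x:.12g}" for x in d.matrix[i]))
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO("\n".join(pdm_csv)), delimiter=","
        )
        ref = pdm.nj_tree()
        ref_splits = set()
        labels = set(d.samples)
        for edge in ref.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf() and edge.tail_node:
                side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
                if 1 < len(side) < len(labels) - 1:
                    other = frozenset(labels - side)
                    ref_splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert ours.splits() == ref_splits


class TestPcGeoCorrelation:
    def _fake_pca(self, ids, pc2):
        from lineage_scope.structure_analysis import PcaResult

        scores = pd.DataFrame({"PC1": np.zeros(len(ids)), "PC2": pc2, "PC3": np.zeros(len(ids))},
                              index=ids)
        return PcaResult(np.ones(3), scores, scores, np.ones(3) / 3)

    def test_perfect_correlation(self):
        ids = [f"s{i}" for i in range(6)]
        lons = np.arange(6.0)
        res = self._fake_pca(ids, lons)
        recs = [SampleRecord(i, "L1", None, lon, 10.0, 100.0) for i, lon in zip(ids, lons)]
        table = pc_geo_correlation(res, recs)
        r = table[(table.component == "PC2") & (table.variable == "longitude")]["r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_orthogonal_vector_zero(self):
        ids = [f"s{i}" for i in range(4)]
        res = self._fake_pca(ids, np.array([1.0, -1.0, 1.0, -1.0]))
        recs = [SampleRecord(i, "L1", None, lon, 10.0, 100.0)
                for i, lon in zip(ids, [1.0, 1.0, -1.0, -1.0])]
        table = pc_geo_correlation(res, recs)
        r = table[(table.component == "PC2") & (table.variable == "longitude")]["r"].iloc[0]
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_pairs_warns_nan(self):
        ids = ["a", "b", "c"]
        res = self._fake_pca(ids, np.arange(3.0))
        recs = [SampleRecord(i, "L1") for i in ids]  # no geography at all
        with pytest.warns(UserWarning):
            table = pc_geo_correlation(res, recs)
        assert table["r"].isna().all()

    def test_planted_longitudinal_cline_recovered(self, default_panel):
        gm, part, records = (default_panel["gm"], default_panel["partition"],
                             default_panel["records"])
        taus = part.samples("L1") + part.samples("L2")
        res = pca(relationship_matrix(gm.subset_samples(taus)))
        l1 = [s for s in part.samples("L1")]
        lon = {r.id: r.longitude for r in records}
        sub = res.scores.loc[l1, "PC2"]
        r = np.corrcoef(sub, [lon[s] for s in l1])[0, 1]
        assert abs(r) >= 0.5
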