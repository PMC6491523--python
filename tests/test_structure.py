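"""Relationship matrix, PCA projection and neighbour-joining trees."""

import dendropy
import numpy as np
import pytest

from pigdiv import (
    PanelConfig,
    ibs_distance,
    nj_tree,
    pca,
    project,
    relationship_matrix,
    simulate_panel,
)
from tests_support_trees import patristic, random_additive_metric


class TestRelationshipMatrix:
    def test_duplicate_rows_identical(self):
        cfg = PanelConfig(n_markers=300, group_spec=(("g", 25, 0.2),),
                          n_duplicates=2, missing_rate=0.0, rng_seed=2)
        gm, truth = simulate_panel(cfg)
        rm = relationship_matrix(gm)
        idx = {a: i for i, a in enumerate(rm.accession_ids)}
        for src, dup in truth.duplicate_pairs:
            np.testing.assert_allclose(rm.A[idx[src]], rm.A[idx[dup]])

    def test_self_value_tracks_inbreeding(self):
        """Mean diagonal of the additive relationship matrix is about 1 + FIS."""
        cfg = PanelConfig(n_markers=2000, group_spec=(("g", 150, 0.0),),
                          selfing_generations=3, missing_rate=0.0, rng_seed=7)
        gm, _ = simulate_panel(cfg)
        rm = relationship_matrix(gm)
        fis_expected = 1 - 0.5**3
        assert abs(np.mean(np.diag(rm.A)) - (1 + fis_expected)) < 0.08

    def test_block_structure_between_groups(self, two_group_panel):
        gm, _ = two_group_panel
        rm = relationship_matrix(gm)
        labels = gm.group_labels("subspecies")
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert rm.A[same & off].mean() > rm.A[~same].mean()

    def test_monomorphic_panel_rejected(self, gm_factory):
        with pytest.raises(ValueError, match="monomorphic"):
            relationship_matrix(gm_factory(np.zeros((4, 6), dtype=int)))


class TestPca:
    def test_pc1_separates_diverged_groups(self, two_group_panel):
        gm, _ = two_group_panel
        res = pca(relationship_matrix(gm), n_pcs=2)
        labels = gm.group_labels("subspecies")
        pc1 = res.scores[:, 0]
        a, b = pc1[labels == "indica"], pc1[labels == "japonica"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            max(b.min(), a.min()) > min(b.max(), a.max())  # disjoint ranges
        assert res.pct_variance[0] > 5 * res.pct_variance[1]

    def test_pct_variance_ordered_and_bounded(self, two_group_panel):
        gm, _ = two_group_panel
        res = pca(relationship_matrix(gm), n_pcs=5)
        assert (np.diff(res.pct_variance) <= 1e-9).all()
        assert res.pct_variance.sum() <= 100.0 + 1e-6

    def test_projection_identity(self, two_group_panel):
        gm, _ = two_group_panel
        res = pca(relationship_matrix(gm), n_pcs=4)
        proj = project(res, gm)
        np.testing.assert_allclose(proj, res.scores, atol=1e-8)

    def test_duplicate_projects_to_same_point(self):
        cfg = PanelConfig(n_markers=400, group_spec=(("g", 30, 0.3),),
                          n_duplicates=1, missing_rate=0.0, rng_seed=5)
        gm, truth = simulate_panel(cfg)
        src, dup = truth.duplicate_pairs[0]
        ref = gm.take_accessions([a for a in gm.accession_ids if a != dup])
        res = pca(relationship_matrix(ref), n_pcs=3)
        proj = project(res, gm.take_accessions([dup]))
        i = res.accession_ids.index(src)
        np.testing.assert_allclose(proj[0], res.scores[i], atol=1e-8)

    def test_no_common_markers_rejected(self, two_group_panel, gm_factory):
        gm, _ = two_group_panel
        res = pca(relationship_matrix(gm), n_pcs=2)
        stranger = gm_factory([[0, 1], [2, 0]], marker_ids=["zz1", "zz2"])
        with pytest.raises(ValueError, match="shared"):
            project(res, stranger)


class TestNjTree:
    def test_four_taxon_exact_recovery(self):
        # metric of ((A:1,B:2):3,(C:4,D:5)) with internal edge 3
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        tree = nj_tree(D, ["A", "B", "C", "D"])
        np.testing.assert_allclose(patristic(tree, ["A", "B", "C", "D"]), D, atol=1e-9)
        assert tree.bipartitions() == {frozenset({"A", "B"})}

    def test_star_metric_zero_internal_edge(self):
        D = np.ones((4, 4)) * 2.0
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(D, list("ABCD"))
        dt = tree.as_dendropy()
        internal = [e.length for e in dt.preorder_edge_iter()
                    if e.head_node.is_internal() and e.length is not None]
        assert all(abs(x) < 1e-9 for x in internal)

    def test_random_additive_metrics_recovered(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 17))
            taxa, D = random_additive_metric(n, rng)
            tree = nj_tree(D, taxa)
            np.testing.assert_allclose(patristic(tree, taxa), D, atol=1e-6)

    def test_agrees_with_dendropy_nj_topology(self, two_group_panel):
        gm, _ = two_group_panel
        sub = gm.take_accessions(gm.accession_ids[:10] + gm.accession_ids[-10:])
        dist, _ = ibs_distance(sub)
        tree = nj_tree(dist, sub.accession_ids)

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_dist_csv(dist, sub.accession_ids), delimiter=",")
        ref = pdm.nj_tree()
        ref_biparts = set()
        ref.encode_bipartitions()
        labels = frozenset(sub.accession_ids)
        for edge in ref.preorder_edge_iter():
            if edge.head_node.is_internal() and edge.tail_node is not None:
                side = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
                if 1 < len(side) < len(labels) - 1:
                    side = side if sub.accession_ids[0] not in side else labels - side
                    ref_biparts.add(side)
        mine = {b if sub.accession_ids[0] not in b else labels - b
                for b in tree.bipartitions()}
        assert mine == ref_biparts

    def test_bootstrap_supports_planted_split(self, two_group_panel):
        gm, _ = two_group_panel
        sub = gm.take_accessions(gm.accession_ids[:6] + gm.accession_ids[-6:])
        dist, _ = ibs_distance(sub)
        tree = nj_tree(dist, sub.accession_ids, boot=(sub, 50, 3))
        labels = frozenset(sub.accession_ids)
        split = frozenset(sub.accession_ids[:6])
        canon = {b if sub.accession_ids[0] not in b else labels - b: s
                 for b, s in tree.supports.items()}
        key = split if sub.accession_ids[0] not in split else labels - split
        assert canon[key] >= 95.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


def _dist_csv(dist, ids):
    import io
    buf = io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i, a in enumerate(ids):
        buf.write(a + "," + ",".join(f"{dist[i, j]:.10f}" for j in range(len(ids))) + "\n")
    buf.seek(0)
    return buf
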