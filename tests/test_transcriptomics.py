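"""Sphere mapping, donor-median normalization, permutation testing."""

import numpy as np
import pytest

import ageatlas as aa
from ageatlas.synthetic_data import ExpressionDataset
from ageatlas.transcriptomics import (collapse_probes, map_samples_to_clusters,
                                      normalize_expression,
                                      permutation_gene_association,
                                      select_genes, voxelize_sphere)


class TestVoxelizeSphere:
    def test_subvoxel_radius_hits_one_voxel(self):
        vox = voxelize_sphere(np.array([2.0, 2.0, 2.0]), 0.4, (5, 5, 5),
                              np.eye(4))
        assert vox.shape == (1, 3)
        assert np.array_equal(vox[0], [2, 2, 2])

    def test_matches_exhaustive_scan(self):
        # 6-mm sphere on a 1.5-mm grid vs a brute-force scan of every voxel
        affine = np.diag([1.5, 1.5, 1.5, 1.0])
        affine[:3, 3] = -10.0
        shape = (15, 15, 15)
        center = np.array([1.5 * 7 - 10.0] * 3)  # a voxel center
        got = voxelize_sphere(center, 6.0, shape, affine)
        brute = []
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    world = affine[:3, :3] @ [i, j, k] + affine[:3, 3]
                    if np.sum((world - center) ** 2) <= 36.0:
                        brute.append((i, j, k))
        assert sorted(map(tuple, got)) == sorted(brute)

    def test_translation_by_one_voxel_shifts_set(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        a = voxelize_sphere(np.array([10.0, 10.0, 10.0]), 5.0, (20, 20, 20),
                            affine)
        b = voxelize_sphere(np.array([12.0, 10.0, 10.0]), 5.0, (20, 20, 20),
                            affine)
        assert np.array_equal(a + [1, 0, 0], b)

    def test_outside_grid_is_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="ageatlas.transcriptomics"):
            vox = voxelize_sphere(np.array([1e4, 1e4, 1e4]), 3.0, (5, 5, 5),
                                  np.eye(4))
        assert vox.size == 0
        assert any("outside the grid" in m for m in caplog.messages)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            voxelize_sphere(np.zeros(3), 0.0, (5, 5, 5), np.eye(4))


class TestMapSamples:
    def test_interior_sample_fully_overlaps(self):
        mask = np.ones((20, 20, 20), dtype=bool)
        labels = np.full((20, 20, 20), 4)
        out = map_samples_to_clusters(np.array([[10.0, 10.0, 10.0]]), mask,
                                      labels, np.eye(4), radius_mm=3.0)
        assert out[0].cluster == 4
        assert out[0].overlap_fraction == 1.0

    def test_far_outside_unassigned(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:3] = True
        labels = mask.astype(int)
        out = map_samples_to_clusters(np.array([[9.0, 9.0, 9.0]]), mask,
                                      labels, np.eye(4), radius_mm=1.0)
        assert out[0].cluster is None

    def test_exact_half_overlap_rejected(self):
        # sphere of exactly two voxels; mask contains exactly one of them:
        # overlap 0.5 is NOT strictly greater than the 0.5 threshold
        affine = np.eye(4)
        center = np.array([2.5, 2.0, 2.0])
        sphere = voxelize_sphere(center, 1.0, (6, 6, 6), affine)
        assert len(sphere) == 2  # the construction this test relies on
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[tuple(sphere[0])] = True
        labels = mask.astype(int)
        out = map_samples_to_clusters(center[None], mask, labels, affine,
                                      radius_mm=1.0, overlap_threshold=0.5)
        assert out[0].overlap_fraction == pytest.approx(0.5)
        assert out[0].cluster is None

    def test_assignment_invariant_to_sample_order(self, paper_scale_atlas,
                                                  expression_with_truth):
        ds, _ = expression_with_truth
        atlas = paper_scale_atlas
        coords = ds.sample_world_coords[:40]
        fwd = map_samples_to_clusters(coords, atlas.mask,
                                      atlas.network_grid(), atlas.affine)
        rev = map_samples_to_clusters(coords[::-1], atlas.mask,
                                      atlas.network_grid(), atlas.affine)
        assert [a.cluster for a in fwd] == [a.cluster for a in rev][::-1]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a grid"):
            map_samples_to_clusters(np.zeros((1, 3)),
                                    np.zeros((3, 3, 3), dtype=bool),
                                    np.zeros((4, 4, 4), dtype=int), np.eye(4))


def _tiny_dataset(expr, donors):
    n_genes, n_samples = expr.shape
    return ExpressionDataset(
        donor_of_sample=donors,
        sample_world_coords=np.zeros((n_samples, 3)),
        expr=expr,
        gene_ids=[f"g{i}" for i in range(n_genes)],
    )


class TestNormalizeExpression:
    def test_three_sample_donor_forced_values(self):
        ds = _tiny_dataset(np.array([[1.0, 2.0, 3.0]]), ["d1"] * 3)
        assert np.allclose(normalize_expression(ds), [[-0.5, 0.0, 0.5]])

    def test_constant_gene_maps_to_zero(self):
        ds = _tiny_dataset(np.full((2, 4), 7.0), ["d1"] * 4)
        assert np.allclose(normalize_expression(ds), 0.0)

    def test_each_donor_uses_own_median(self):
        # donor d1 samples [1,2,3] (median 2), donor d2 samples [10,20,30]
        # (median 20): hand-computed per-donor normalization
        ds = _tiny_dataset(np.array([[1.0, 2.0, 3.0, 10.0, 20.0, 30.0]]),
                           ["d1"] * 3 + ["d2"] * 3)
        want = [[-0.5, 0.0, 0.5, -0.5, 0.0, 0.5]]
        assert np.allclose(normalize_expression(ds), want)

    def test_zero_median_names_gene_and_donor(self):
        ds = _tiny_dataset(np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 1.0]]),
                           ["dX"] * 3)
        with pytest.raises(ValueError, match="g0.*dX"):
            normalize_expression(ds)

    def test_sign_structure(self, expression_with_truth):
        ds, _ = expression_with_truth
        norm = normalize_expression(ds)
        donors = np.asarray(ds.donor_of_sample)
        for d in set(ds.donor_of_sample):
            cols = donors == d
            med = np.median(ds.expr[:, cols], axis=1)
            above = ds.expr[:, cols] > med[:, None]
            assert np.all(norm[:, cols][above] > 0)
            assert np.all(norm[:, cols][~above] <= 0)


def _assignments(clusters):
    from ageatlas.transcriptomics import SampleAssignment
    return [SampleAssignment(i, 10, 1.0, c) for i, c in enumerate(clusters)]


class TestPermutationAssociation:
    def test_extreme_statistic_attains_minimum_p(self):
        # gene far higher in-cluster than any random draw can reach
        rng = np.random.default_rng(0)
        expr = rng.normal(0, 0.1, size=(3, 40))
        expr[0, :5] += 100.0
        assign = _assignments([1] * 5 + [2] * 35)
        out = permutation_gene_association(expr, assign, 1,
                                           [f"g{i}" for i in range(3)],
                                           n_perm=999, seed=1,
                                           alternative="greater")
        assert out[0].p_value == pytest.approx(1 / 1000)

    def test_two_sided_p_and_fwe_bounds(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(10, 60))
        assign = _assignments([1] * 10 + [2] * 50)
        out = permutation_gene_association(expr, assign, 1,
                                           [f"g{i}" for i in range(10)],
                                           n_perm=499, seed=3)
        for a in out:
            assert 0 < a.p_value <= 1
            assert a.p_fwe >= a.p_value

    def test_seed_reproducibility_bitwise(self):
        rng = np.random.default_rng(4)
        expr = rng.normal(size=(5, 30))
        assign = _assignments([1] * 4 + [2] * 26)
        genes = [f"g{i}" for i in range(5)]
        a = permutation_gene_association(expr, assign, 1, genes, n_perm=199,
                                         seed=9)
        b = permutation_gene_association(expr, assign, 1, genes, n_perm=199,
                                         seed=9)
        assert [(x.p_value, x.p_fwe) for x in a] == \
               [(x.p_value, x.p_fwe) for x in b]

    def test_planted_signal_recovered_without_false_positives(
            self, paper_scale_atlas, expression_with_truth):
        ds, truth = expression_with_truth
        atlas = paper_scale_atlas
        assign = map_samples_to_clusters(ds.sample_world_coords, atlas.mask,
                                         atlas.network_grid(), atlas.affine)
        out = permutation_gene_association(
            normalize_expression(ds), assign, truth.target_network,
            ds.gene_ids, n_perm=999, seed=5)
        selected = set(select_genes(out))
        assert set(truth.signal_gene_ids) <= selected
        assert not selected - set(truth.signal_gene_ids)

    def test_degenerate_cluster_rejected(self):
        expr = np.zeros((2, 10))
        assign = _assignments([1] * 9 + [2])
        with pytest.raises(ValueError, match="degenerate cluster"):
            permutation_gene_association(expr, assign, 1, ["a", "b"],
                                         n_perm=199, seed=0)

    def test_bonferroni_option(self):
        rng = np.random.default_rng(6)
        expr = rng.normal(size=(4, 30))
        assign = _assignments([1] * 5 + [2] * 25)
        genes = list("abcd")
        out = permutation_gene_association(expr, assign, 1, genes,
                                          n_perm=199, seed=7,
                                          fwe="bonferroni")
        for a in out:
            assert a.p_fwe == pytest.approx(min(1.0, a.p_value * 4))


class TestSelectGenes:
    def test_all_insignificant_gives_empty(self):
        from ageatlas.transcriptomics import GeneAssociation
        assocs = [GeneAssociation("g", 0.0, 1.0, 1.0, False)]
        assert select_genes(assocs) == []

    def test_alpha_one_returns_all_sorted(self):
        from ageatlas.transcriptomics import GeneAssociation
        assocs = [GeneAssociation("a", 0, 0.5, 0.9, False),
                  GeneAssociation("b", 0, 0.1, 0.2, False)]
        assert select_genes(assocs, alpha=1.01) == ["b", "a"]


def test_collapse_probes_picks_highest_mean():
    expr = np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
    collapsed, genes = collapse_probes(expr, ["gA", "gA", "gB"])
    assert genes == ["gA", "gB"]
    assert np.array_equal(collapsed, [[5.0, 5.0], [2.0, 2.0]])
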