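import numpy as np
import pandas as pd
import pytest

import dietshift as ds


def dmatrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or list(range(len(values)))
    return ds.DissimilarityMatrix(labels, values)


class TestBrayCurtis:
    def test_disjoint_composition_is_one(self):
        D = ds.bray_curtis(pd.DataFrame([[1, 0], [0, 1]]))
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_identical_rows_are_zero(self):
        D = ds.bray_curtis(pd.DataFrame([[3, 2, 5], [3, 2, 5]]))
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_hand_evaluated_formula(self):
        # rows (2,1) vs (1,1): (|2-1| + |1-1|) / (3 + 2) = 0.2
        D = ds.bray_curtis(pd.DataFrame([[2, 1], [1, 1]]))
        assert D.values[0, 1] == pytest.approx(0.2)

    def test_semimetric_properties_on_generated_fo(self, generated_fo):
        D = ds.bray_curtis(generated_fo)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0)
        assert D.values.min() >= 0 and D.values.max() <= 1

    def test_all_zero_row_names_the_year(self):
        df = pd.DataFrame([[1, 2], [0, 0]], index=[2001, 2002])
        with pytest.raises(ValueError, match="2002"):
            ds.bray_curtis(df)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ds.bray_curtis(pd.DataFrame([[1, -1], [1, 1]]))


def naive_ward_d2(d):
    """Independent Lance-Williams ward.D2 agglomeration (O(n^3) reference).

    d(k, i+j)^2 = ((n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2 - n_k d(i,j)^2)
                  / (n_i+n_j+n_k)
    """
    d = np.array(d, dtype=float)
    active = {i: (1, (i,)) for i in range(len(d))}
    d2 = d ** 2
    merges = []
    dist = {(i, j): d2[i, j] for i in active for j in active if i < j}
    next_id = len(d)
    while len(active) > 1:
        (i, j), dij2 = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ni, mi = active.pop(i)
        nj, mj = active.pop(j)
        merges.append((set(mi) | set(mj), np.sqrt(dij2)))
        new = next_id
        next_id += 1
        for k, (nk, _) in active.items():
            dik2 = dist.pop((min(i, k), max(i, k)))
            djk2 = dist.pop((min(j, k), max(j, k)))
            dist[(k, new)] = ((ni + nk) * dik2 + (nj + nk) * djk2
                              - nk * dij2) / (ni + nj + nk)
        dist = {key: v for key, v in dist.items()
                if i not in key and j not in key}
        active[new] = (ni + nj, mi + mj)
    return merges


def scipy_merges(dend):
    n = len(dend.labels)
    members = {i: {i} for i in range(n)}
    out = []
    for row_idx, (a, b, height, _) in enumerate(dend.linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append((merged, height))
    return out


class TestWardClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        df = pd.DataFrame([[1, 2], [1, 2], [5, 0]], index=["a", "b", "c"])
        dend = ds.ward_cluster(ds.bray_curtis(df))
        first_members, first_height = scipy_merges(dend)[0]
        assert first_members == {0, 1}
        assert first_height == pytest.approx(0.0, abs=1e-12)

    def test_four_point_instance_matches_independent_lance_williams(self):
        d = np.array([
            [0.0, 0.2, 0.7, 0.8],
            [0.2, 0.0, 0.6, 0.9],
            [0.7, 0.6, 0.0, 0.3],
            [0.8, 0.9, 0.3, 0.0],
        ])
        dend = ds.ward_cluster(dmatrix(d))
        for (got_m, got_h), (ref_m, ref_h) in zip(
                scipy_merges(dend), naive_ward_d2(d)):
            assert got_m == ref_m
            assert got_h == pytest.approx(ref_h)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_independent_lance_williams(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((7, 4))
        d = ds.bray_curtis(pd.DataFrame(x)).values
        dend = ds.ward_cluster(dmatrix(d))
        for (got_m, got_h), (ref_m, ref_h) in zip(
                scipy_merges(dend), naive_ward_d2(d)):
            assert got_m == ref_m
            assert got_h == pytest.approx(ref_h)

    def test_merge_heights_non_decreasing(self, generated_fo):
        dend = ds.ward_cluster(ds.bray_curtis(generated_fo))
        heights = dend.merge_heights()
        assert (np.diff(heights) >= -1e-12).all()

    def test_two_regime_fo_matrix_splits_at_the_break(self, catalog):
        """A k=2 cut of the year dendrogram should separate pre- and
        post-shift years of generator output in nearly all seeds."""
        hits = 0
        seeds = range(12)
        for seed in seeds:
            table = ds.generate_samples(seed=seed)
            fo = ds.occurrence_frequencies(table, catalog=catalog)
            dend = ds.ward_cluster(ds.bray_curtis(fo))
            cut = dend.cut(2)
            pre = {c for y, c in cut.items() if y <= 2006}
            post = {c for y, c in cut.items() if y > 2006}
            hits += len(pre) == 1 and len(post) == 1 and pre != post
        assert hits >= 0.9 * len(seeds)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            ds.ward_cluster(dmatrix([[0.0]], labels=["x"]))

    def test_newick_round_trips_leaves_and_heights(self, generated_fo):
        dend = ds.ward_cluster(ds.bray_curtis(generated_fo))
        newick = dend.to_newick()
        import io

        from Bio import Phylo
        tree = Phylo.read(io.StringIO(newick), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == {str(y) for y in generated_fo.index}
        # path length from root to any leaf equals the root merge height
        root_height = dend.merge_heights()[-1]
        for leaf in tree.get_terminals():
            assert tree.distance(leaf) == pytest.approx(root_height, rel=1e-4)


class TestNMDS:
    def test_three_points_embed_exactly_in_two_dims(self):
        D = dmatrix([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        res = ds.nmds(D, k=2, seed=0, n_restarts=4)
        assert res.stress < 1e-3

    def test_euclidean_configuration_reembeds_with_low_stress(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        coords = rng.random((10, 2))
        d = squareform(pdist(coords))
        d /= d.max()
        res = ds.nmds(dmatrix(d), k=2, seed=0)
        assert res.stress < 0.01

    def test_stress_non_increasing_in_dimensions(self):
        # a genuinely 4-D configuration, so lower k must fit strictly worse
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.normal(size=(12, 4))))
        D = dmatrix(d / d.max())
        stresses = [ds.nmds(D, k=k, seed=0, n_restarts=8).stress
                    for k in (1, 2, 3)]
        assert stresses[1] <= stresses[0] + 1e-3
        assert stresses[2] <= stresses[1] + 1e-3

    def test_coordinates_centered_and_deterministic(self, generated_fo):
        D = ds.bray_curtis(generated_fo)
        r1 = ds.nmds(D, seed=3, n_restarts=4)
        r2 = ds.nmds(D, seed=3, n_restarts=4)
        np.testing.assert_allclose(r1.coordinates, r2.coordinates)
        np.testing.assert_allclose(r1.coordinates.mean(), 0, atol=1e-9)

    def test_invalid_dimension_rejected(self):
        D = dmatrix([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            ds.nmds(D, k=2)


class TestSpeciesScores:
    coords = pd.DataFrame({"dim1": [1.0, -1.0, 0.0], "dim2": [0.0, 2.0, -2.0]},
                          index=[2001, 2002, 2003])

    def test_single_year_taxon_sits_on_that_year(self):
        fo = pd.DataFrame({"only2002": [0, 40, 0]}, index=self.coords.index)
        scores = ds.species_scores(self.coords, fo)
        np.testing.assert_allclose(scores.loc["only2002"],
                                   self.coords.loc[2002])

    def test_uniform_taxon_sits_at_centroid(self):
        fo = pd.DataFrame({"everywhere": [30, 30, 30]},
                          index=self.coords.index)
        scores = ds.species_scores(self.coords, fo)
        np.testing.assert_allclose(scores.loc["everywhere"],
                                   self.coords.mean(), atol=1e-12)

    def test_three_to_one_weighting_interpolates(self):
        fo = pd.DataFrame({"t": [30, 10, 0]}, index=self.coords.index)
        scores = ds.species_scores(self.coords, fo)
        expected = 0.75 * self.coords.loc[2001] + 0.25 * self.coords.loc[2002]
        np.testing.assert_allclose(scores.loc["t"], expected)

    def test_never_observed_taxon_omitted_with_warning(self):
        fo = pd.DataFrame({"ghost": [0, 0, 0], "t": [1, 1, 1]},
                          index=self.coords.index)
        with pytest.warns(UserWarning, match="ghost"):
            scores = ds.species_scores(self.coords, fo)
        assert "ghost" not in scores.index
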