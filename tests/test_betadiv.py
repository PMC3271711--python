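import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from temporalcore.betadiv import (
    adjacent_delta_series,
    correlate_delta_series,
    ordination_trace,
    paired_distance_correlation,
    pcoa,
    procrustes_test,
    unweighted_unifrac,
    within_between_test,
)
from temporalcore.synth import SynthParams, generate_dataset, _random_subtree
from temporalcore.tables_io import CountTable, SampleRecord
from oracles import branch_partition_unifrac


def _table(presence, otu_ids, sample_ids):
    return CountTable(pd.DataFrame(
        np.asarray(presence, dtype=int) * 7, index=otu_ids, columns=sample_ids))


def _star_tree(tip_names, length=1.0):
    return TreeNode(children=[TreeNode(name=t, length=length)
                              for t in tip_names])


class TestUnifrac:
    def test_identical_profiles_zero(self):
        tree = _star_tree(["a", "b", "c"])
        t = _table([[1, 1], [0, 0], [1, 1]], ["a", "b", "c"], ["s1", "s2"])
        dm = unweighted_unifrac(tree, t)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_star_communities_one(self):
        tree = _star_tree(["a", "b", "c", "d"])
        t = _table([[1, 0], [1, 0], [0, 1], [0, 1]],
                   ["a", "b", "c", "d"], ["s1", "s2"])
        dm = unweighted_unifrac(tree, t)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_missing_tip_rejected(self):
        tree = _star_tree(["a", "b"])
        t = _table([[1, 0], [0, 1]], ["a", "zzz"], ["s1", "s2"])
        with pytest.raises(ValueError, match="zzz"):
            unweighted_unifrac(tree, t)

    def test_matches_branch_partition_oracle(self, rng):
        for _ in range(100):
            tips = [f"t{i}" for i in range(8)]
            tree = _random_subtree(rng, tips)
            presence = rng.random((8, 3)) < 0.5
            t = _table(presence, tips, ["u", "v", "w"])
            dm = unweighted_unifrac(tree, t)
            for i, j in ((0, 1), (0, 2), (1, 2)):
                set_i = {tips[k] for k in range(8) if presence[k, i]}
                set_j = {tips[k] for k in range(8) if presence[k, j]}
                expected = branch_partition_unifrac(tree, set_i, set_j)
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-9)

    def test_matches_skbio_reference(self, rng):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        tips = [f"t{i}" for i in range(10)]
        tree = _random_subtree(rng, tips)
        tree.length = None
        counts = rng.integers(0, 5, size=(10, 6))
        t = _table(counts > 0, tips, [f"s{i}" for i in range(6)])
        dm = unweighted_unifrac(tree, t)
        ref = skbio_diversity.beta_diversity(
            "unweighted_unifrac", t.counts.T, ids=t.sample_ids,
            taxa=tips, tree=tree)
        assert np.allclose(dm.data, ref.data, atol=1e-9)


class TestPcoa:
    def test_reconstructs_euclidean_distances(self, rng):
        for _ in range(20):
            points = rng.normal(size=(rng.integers(4, 15), 3))
            dm = DistanceMatrix(squareform(pdist(points)),
                                ids=[str(i) for i in range(len(points))])
            res = pcoa(dm)
            recon = squareform(pdist(res.coordinates))
            assert np.allclose(recon, dm.data, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = pcoa(dm)
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-9)

    def test_eigenvalues_descending_and_proportions(self, rng):
        pts = rng.normal(size=(10, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        res = pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestProcrustes:
    def test_similarity_transform_gives_zero(self, rng):
        a = rng.normal(size=(12, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        b = 2.5 * a @ rot + np.array([3.0, -1.0, 0.5])
        ids = [str(i) for i in range(12)]
        res = procrustes_test(pd.DataFrame(a, index=ids),
                              pd.DataFrame(b, index=ids),
                              n_axes=3, n_permutations=99, seed=0)
        assert res.m_squared == pytest.approx(0.0, abs=1e-10)
        assert res.p_value >= 1 / 100

    def test_unmatched_ids_rejected(self):
        a = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        b = pd.DataFrame(np.eye(3), index=["a", "b", "z"])
        with pytest.raises(ValueError):
            procrustes_test(a, b, n_axes=2, n_permutations=9, seed=0)

    def test_p_respects_add_one_floor(self, rng):
        ids = [str(i) for i in range(10)]
        a = pd.DataFrame(rng.normal(size=(10, 3)), index=ids)
        b = pd.DataFrame(rng.normal(size=(10, 3)), index=ids)
        res = procrustes_test(a, b, n_axes=3, n_permutations=49, seed=1)
        assert res.p_value >= 1 / 50


class TestPairedDistanceCorrelation:
    def test_self_correlation_is_one(self, rng):
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        r, p = paired_distance_correlation(dm, dm, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        d = squareform(pdist(pts))
        ids = [str(i) for i in range(12)]
        dm_a = DistanceMatrix(d, ids=ids)
        dm_b = DistanceMatrix(2.0 * d, ids=ids)
        r, _ = paired_distance_correlation(dm_a, dm_b, n_permutations=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_independent_matrices_uncorrelated(self, rng):
        rs = []
        for _ in range(20):
            d1 = squareform(pdist(rng.normal(size=(30, 3))))
            d2 = squareform(pdist(rng.normal(size=(30, 3))))
            ids = [str(i) for i in range(30)]
            r, p = paired_distance_correlation(
                DistanceMatrix(d1, ids=ids), DistanceMatrix(d2, ids=ids),
                n_permutations=99, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1


class TestDeltaSeries:
    def _dm_records(self, n=8, subject="M3", habitat="left palm", seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        ids = [f"{subject}.{habitat}.{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        records = [SampleRecord(ids[i], subject, habitat, i + 1) for i in range(n)]
        return dm, records

    def test_n_minus_one_deltas(self):
        dm, records = self._dm_records(n=8)
        series = adjacent_delta_series(dm, records, "M3", "left palm")
        assert len(series.deltas) == 7
        assert all(a < b for a, b in series.day_pairs)

    def test_identical_samples_zero_deltas(self):
        ids = ["a", "b", "c"]
        dm = DistanceMatrix(np.zeros((3, 3)), ids=ids)
        records = [SampleRecord(i, "M3", "gut", d + 1) for d, i in enumerate(ids)]
        series = adjacent_delta_series(dm, records, "M3", "gut")
        assert all(d == 0 for d in series.deltas)

    def test_self_correlation(self):
        dm, records = self._dm_records()
        series = adjacent_delta_series(dm, records, "M3", "left palm")
        r, _ = correlate_delta_series(series, series)
        assert r == pytest.approx(1.0)

    def test_alignment_drops_unshared_pairs(self):
        dm_a, rec_a = self._dm_records(n=10, habitat="left palm")
        dm_b, rec_b = self._dm_records(n=10, habitat="right palm", seed=1)
        # right palm misses day 5: pairs (4,5) and (5,6) exist only on the left
        rec_b = [r for r in rec_b if r.day != 5]
        dm_b = dm_b.filter([r.sample_id for r in rec_b])
        ser_a = adjacent_delta_series(dm_a, rec_a, "M3", "left palm")
        ser_b = adjacent_delta_series(dm_b, rec_b, "M3", "right palm")
        shared = set(ser_a.day_pairs) & set(ser_b.day_pairs)
        assert (4, 5) not in shared and (5, 6) not in shared
        r, p = correlate_delta_series(ser_a, ser_b)
        assert np.isfinite(r)

    def test_coupled_palms_correlate_in_synthetic_data(self, small_dataset):
        ds = small_dataset
        sub = [r for r in ds.records if r.subject == "S1"
               and r.habitat in ("left palm", "right palm")]
        table = ds.table.select_samples([r.sample_id for r in sub])
        dm = unweighted_unifrac(ds.tree, table)
        ser_l = adjacent_delta_series(dm, sub, "S1", "left palm")
        ser_r = adjacent_delta_series(dm, sub, "S1", "right palm")
        r_coupled, p = correlate_delta_series(ser_l, ser_r)
        assert r_coupled > 0.3
        assert p < 0.05


class TestWithinBetween:
    @staticmethod
    def _two_subject_dm(rng, n_per=12, shift=0.0):
        subjects = ["S1"] * n_per + ["S2"] * n_per
        ids = [f"s{i}" for i in range(2 * n_per)]
        records = [SampleRecord(ids[i], subjects[i], "gut", i + 1)
                   for i in range(2 * n_per)]
        n = 2 * n_per
        d = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals = rng.normal(0.5, 0.1, size=len(iu[0]))
        cross = np.not_equal(*np.meshgrid(subjects, subjects, indexing="ij"))
        vals = vals + shift * cross[iu]
        d[iu] = np.clip(vals, 0.01, None)
        d = d + d.T
        return DistanceMatrix(d, ids=ids), records

    def test_shifted_between_pool_detected(self, rng):
        dm, records = self._two_subject_dm(rng, n_per=15, shift=0.2)
        res = within_between_test(dm, records, ("S1", "gut"),
                                  (("S1", "gut"), ("S2", "gut")), tail="less")
        assert res.p < 0.001
        assert res.t < 0

    def test_tail_swap_flips_p(self, rng):
        dm, records = self._two_subject_dm(rng, n_per=10)
        less = within_between_test(dm, records, ("S1", "gut"),
                                   (("S1", "gut"), ("S2", "gut")), tail="less")
        greater = within_between_test(dm, records, ("S1", "gut"),
                                      (("S1", "gut"), ("S2", "gut")),
                                      tail="greater")
        assert less.p + greater.p == pytest.approx(1.0)

    def test_empty_pool_rejected(self, rng):
        dm, records = self._two_subject_dm(rng, n_per=5)
        with pytest.raises(ValueError):
            within_between_test(dm, records, ("S3", "gut"),
                                ("S1", "gut"), tail="less")

    def test_synthetic_habitat_divergence(self, small_dataset):
        ds = small_dataset
        sub = [r for r in ds.records if r.habitat == "gut"]
        table = ds.table.select_samples([r.sample_id for r in sub])
        dm = unweighted_unifrac(ds.tree, table)
        res = within_between_test(dm, sub, ("S1", "gut"),
                                  (("S1", "gut"), ("S2", "gut")), tail="less")
        assert res.p < 0.001


def test_ordination_trace_is_time_ordered(small_dataset):
    ds = small_dataset
    sub = [r for r in ds.records if r.subject == "S1" and r.habitat == "gut"]
    table = ds.table.select_samples([r.sample_id for r in sub])
    dm = unweighted_unifrac(ds.tree, table)
    res = pcoa(dm)
    trace = ordination_trace(res, sub, "S1", "gut")
    assert list(trace["day"]) == sorted(trace["day"])
    assert {"PC1", "PC2", "PC3"} <= set(trace.columns)
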