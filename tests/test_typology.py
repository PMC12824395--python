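"""Weighted Ward, PAM, silhouettes and typology selection/naming."""

import numpy as np
import pytest

from medseq.ssa_core import DissimilarityMatrix, dissimilarity_matrix, transition_rates, trate_costs
from medseq.states import ALPHABET, LACK, LITHIUM, STATE_INDEX
from medseq.typology import (
    ClusterSolution,
    cluster_medoids,
    name_typologies,
    pam_cluster,
    pam_objective,
    select_typologies,
    silhouette,
    ward_cluster,
)

from _helpers import archetype_instance, exhaustive_pam_objective


def _dissim(D, w=None, seqs=None):
    D = np.asarray(D, dtype=float)
    n = len(D)
    return DissimilarityMatrix(
        matrix=D,
        weights=np.ones(n) if w is None else np.asarray(w, dtype=float),
        sequences=np.zeros((n, 2), dtype=np.int64) if seqs is None else seqs,
        alphabet=ALPHABET,
    )


def _two_blobs():
    # points 0,1,2 mutually close; 3,4 mutually close; blocks far apart
    D = np.array(
        [
            [0, 1, 1.2, 9, 9.5],
            [1, 0, 0.8, 8.7, 9.1],
            [1.2, 0.8, 0, 9.3, 8.8],
            [9, 8.7, 9.3, 0, 1.1],
            [9.5, 9.1, 8.8, 1.1, 0],
        ]
    )
    return _dissim(D)


class TestWard:
    def test_separable_two_groups(self):
        sol = ward_cluster(_two_blobs(), 2)
        assert sol.labels[0] == sol.labels[1] == sol.labels[2]
        assert sol.labels[3] == sol.labels[4] != sol.labels[0]

    def test_k_equals_n_singletons(self):
        sol = ward_cluster(_two_blobs(), 5)
        assert sorted(sol.labels) == [1, 2, 3, 4, 5]

    def test_matches_scipy_on_unweighted_euclidean(self):
        """With unit weights the in-package agglomeration reproduces
        scipy's ward linkage partition."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.normal(0, 0.3, (6, 2)), rng.normal(4, 0.3, (6, 2)),
             rng.normal((0, 5), 0.3, (6, 2))]
        )
        D = squareform(pdist(pts))
        ours = ward_cluster(_dissim(D), 3).labels
        ref = fcluster(linkage(pdist(pts), method="ward"), 3, criterion="maxclust")
        # same partition up to label renaming
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(ours, ref) == 1.0

    def test_weighted_equals_expanded_duplicates(self):
        D = _two_blobs().matrix
        w = np.array([3, 1, 2, 1, 2], dtype=float)
        weighted = ward_cluster(_dissim(D, w), 2).labels
        reps = np.repeat(np.arange(5), w.astype(int))
        D_exp = D[np.ix_(reps, reps)]
        expanded = ward_cluster(_dissim(D_exp), 2).labels
        # expanded copies of one point agree, and the induced partition matches
        firsts = np.searchsorted(reps, np.arange(5))
        for i, f in enumerate(firsts):
            block = expanded[reps == i]
            assert (block == block[0]).all()
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(weighted, expanded[firsts]) == 1.0


class TestPam:
    def test_separable_two_groups(self):
        sol = pam_cluster(_two_blobs(), 2)
        assert sol.labels[0] == sol.labels[1] == sol.labels[2] != sol.labels[3]
        assert sol.labels[3] == sol.labels[4]

    def test_matches_exhaustive_on_structured_instances(self):
        for seed in range(15):
            dissim, k = archetype_instance(seed)
            if dissim.n_unique <= k:
                continue
            sol = pam_cluster(dissim, k)
            got = pam_objective(dissim, sol.medoids)
            best = exhaustive_pam_objective(dissim.matrix, dissim.weights, k)
            assert got == pytest.approx(best)

    def test_duplicate_heavy_medoid_is_central(self):
        """With weights, the optimal medoid set follows the weighted
        objective, verified by enumeration."""
        D = _two_blobs().matrix
        w = np.array([1, 5, 1, 1, 3], dtype=float)
        sol = pam_cluster(_dissim(D, w), 2)
        assert pam_objective(_dissim(D, w), sol.medoids) == pytest.approx(
            exhaustive_pam_objective(D, w, 2)
        )
        assert set(sol.medoids) == {1, 4}

    def test_perfect_init_is_fixed_point(self):
        dis = _two_blobs()
        init = np.array([1, 1, 1, 2, 2])
        sol = pam_cluster(dis, 2, init=init)
        assert sol.method == "ward_then_pam"
        np.testing.assert_array_equal(np.sort(np.unique(sol.labels)), [1, 2])
        assert (sol.labels[:3] == sol.labels[0]).all()

    def test_objective_never_increases(self, monkeypatch):
        rng = np.random.default_rng(11)
        A = rng.random((12, 12)) * 4
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        dis = _dissim(D)
        sol = pam_cluster(dis, 3)
        # final objective cannot beat BUILD's start in the wrong direction
        from medseq.typology import _pam_build

        start = pam_objective(dis, _pam_build(D, dis.weights, 3))
        assert pam_objective(dis, sol.medoids) <= start + 1e-12

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            pam_cluster(_two_blobs(), 6)

    def test_weighted_equals_expanded_duplicates(self):
        D = _two_blobs().matrix
        w = np.array([2, 1, 3, 2, 1], dtype=float)
        sol_w = pam_cluster(_dissim(D, w), 2)
        reps = np.repeat(np.arange(5), w.astype(int))
        D_exp = D[np.ix_(reps, reps)]
        sol_e = pam_cluster(_dissim(D_exp), 2)
        assert pam_objective(_dissim(D, w), sol_w.medoids) == pytest.approx(
            pam_objective(_dissim(D_exp, np.ones(len(reps))), sol_e.medoids)
        )


class TestSilhouette:
    def test_hand_computed_four_points(self):
        D = np.array(
            [
                [0, 1, 4, 5],
                [1, 0, 3, 4],
                [4, 3, 0, 2],
                [5, 4, 2, 0],
            ],
            dtype=float,
        )
        s, asw = silhouette(_dissim(D), np.array([1, 1, 2, 2]))
        expected = np.array([7 / 9, 5 / 7, 3 / 7, 5 / 9])
        np.testing.assert_allclose(s, expected)
        assert asw == pytest.approx(expected.mean())

    def test_separable_close_to_one(self):
        _, asw = silhouette(_two_blobs(), np.array([1, 1, 1, 2, 2]))
        assert asw > 0.8

    def test_degenerate_identical_points_zero(self):
        D = np.zeros((3, 3))
        s, asw = silhouette(_dissim(D), np.array([1, 1, 2]))
        assert np.allclose(s, 0.0) and asw == 0.0

    def test_singleton_cluster_zero(self):
        s, _ = silhouette(_two_blobs(), np.array([1, 1, 1, 1, 2]))
        assert s[4] == 0.0

    def test_weighted_equals_expanded(self):
        D = _two_blobs().matrix
        w = np.array([2, 3, 1, 2, 2], dtype=float)
        labels = np.array([1, 1, 1, 2, 2])
        s_w, asw_w = silhouette(_dissim(D, w), labels)
        reps = np.repeat(np.arange(5), w.astype(int))
        s_e, asw_e = silhouette(_dissim(D[np.ix_(reps, reps)]), labels[reps])
        firsts = np.searchsorted(reps, np.arange(5))
        np.testing.assert_allclose(s_w, s_e[firsts])
        assert asw_w == pytest.approx(asw_e)


class TestSelection:
    def test_best_matches_table_maximum(self):
        dissim, k = archetype_instance(3)
        best, table = select_typologies(dissim, range(2, min(6, dissim.n_unique) + 1))
        assert best.asw == pytest.approx(table["asw"].max())

    def test_tie_breaks_toward_smaller_k_and_pam(self):
        # all-identical distances: every solution has asw 0; first wins
        D = np.ones((6, 6)) - np.eye(6)
        best, table = select_typologies(_dissim(D), range(2, 5))
        assert best.k == 2 and best.method == "pam"

    def test_no_structure_is_low_asw(self):
        D = np.ones((8, 8)) - np.eye(8)
        best, _ = select_typologies(_dissim(D), range(2, 5))
        assert best.asw <= 0.05


class TestNaming:
    def _dissim_from(self, seqs):
        arr = np.array(seqs, dtype=object)
        return dissimilarity_matrix(arr, trate_costs(transition_rates(arr)))

    def test_medoid_dominant_state_names(self):
        seqs = [[LACK] * 12] * 4 + [[LITHIUM] * 12] * 4
        dis = self._dissim_from(seqs)
        sol = pam_cluster(dis, 2)
        names = set(name_typologies(sol, dis).values())
        assert names == {"treatment failure", "persistent lithium"}

    def test_ambiguous_medoid_unclassified(self):
        seqs = [[LACK] * 6 + [LITHIUM] * 6, [LITHIUM] * 6 + [LACK] * 6]
        dis = self._dissim_from(seqs)
        sol = ClusterSolution(
            "pam", 2, np.array([1, 2]), np.array([0, 1]),
            np.zeros(2), 0.0,
        )
        with pytest.warns(UserWarning, match="ambiguous"):
            names = name_typologies(sol, dis)
        assert set(names.values()) == {"unclassified"}

    def test_ward_solution_uses_cluster_medoids(self):
        seqs = [[LACK] * 12] * 3 + [[LITHIUM] * 12] * 3
        dis = self._dissim_from(seqs)
        sol = ward_cluster(dis, 2)
        med = cluster_medoids(dis, sol.labels)
        assert set(med.keys()) == {1, 2}
        names = name_typologies(sol, dis)
        assert set(names.values()) == {"treatment failure", "persistent lithium"}
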