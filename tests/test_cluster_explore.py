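"""Distances, fanny-style fuzzy clustering, classical MDS, diagnostics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from dolloloss.cluster_explore import (
    DistanceMatrix,
    classical_mds,
    cluster_diagnostics,
    fuzzy_cluster,
    pairwise_distances,
    reduce_and_partition,
)
from dolloloss.toga_io import PresenceMatrix

from conftest import random_matrix


def _blob_distances(rng, sizes=(5, 5), separation=50.0, noise=1.0):
    """Distance matrix of well-separated point blobs, plus true labels."""
    points, labels = [], []
    for b, size in enumerate(sizes):
        center = np.array([b * separation, 0.0])
        points.extend(center + rng.normal(scale=noise, size=(size, 2)))
        labels.extend([b] * size)
    points = np.asarray(points)
    names = [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(names, squareform(pdist(points))), dict(zip(names, labels))


class TestDistances:
    def test_manhattan_counts_mismatches(self):
        m = PresenceMatrix(
            ["x", "y"], list("abcd"), np.array([[1, 0, 1, 1], [1, 1, 0, 1]])
        )
        D = pairwise_distances(m, "manhattan")
        assert D.d[0, 1] == 2.0
        assert D.d[0, 0] == 0.0

    def test_full_matrix_matches_loop_oracle(self, rng):
        m = random_matrix(rng, ["s1", "s2", "s3"], 20)
        D = pairwise_distances(m, "manhattan")
        for i in range(3):
            for j in range(3):
                expected = sum(
                    abs(int(a) - int(b)) for a, b in zip(m.states[i], m.states[j])
                )
                assert D.d[i, j] == expected

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValueError, match="metric"):
            pairwise_distances(random_matrix(rng, ["a", "b"], 4), "cosine")


class TestFuzzy:
    def test_separated_blobs_get_confident_memberships(self, rng):
        D, labels = _blob_distances(rng)
        model = fuzzy_cluster(D, K=2, m=1.5, seed=1)
        hard = model.hard_labels()
        # max membership at least 0.9 within the member's own group
        assert model.U.max(axis=1).min() >= 0.9
        # partition matches the blobs (up to cluster relabeling)
        groups = {}
        for name, lab in hard.items():
            groups.setdefault(labels[name], set()).add(lab)
        assert all(len(g) == 1 for g in groups.values())
        assert groups[0] != groups[1]

    def test_membership_rows_sum_to_one(self, rng):
        D, _ = _blob_distances(rng, sizes=(4, 4, 4), separation=10, noise=2)
        model = fuzzy_cluster(D, K=3, m=1.2, seed=0)
        assert np.allclose(model.U.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_nonincreasing(self, rng):
        for trial in range(5):
            m = random_matrix(rng, [f"s{i}" for i in range(10)], 40)
            D = pairwise_distances(m, "manhattan")
            model = fuzzy_cluster(D, K=3, m=1.4, seed=trial)
            trace = model.objective_trace
            assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_degenerate_parameters_rejected(self, rng):
        D, _ = _blob_distances(rng)
        with pytest.raises(ValueError, match="K must"):
            fuzzy_cluster(D, K=1)
        with pytest.raises(ValueError, match="K must"):
            fuzzy_cluster(D, K=len(D.labels))
        with pytest.raises(ValueError, match="fuzzifier"):
            fuzzy_cluster(D, K=2, m=1.0)


class TestMds:
    def test_planar_configuration_recovered_exactly(self, rng):
        points = rng.normal(size=(7, 2))
        D = DistanceMatrix([f"p{i}" for i in range(7)], squareform(pdist(points)))
        res = classical_mds(D, dims=2)
        rebuilt = squareform(pdist(res.coordinates.values))
        assert np.abs(rebuilt - D.d).max() < 1e-8

    def test_collinear_points_order_preserved_on_axis1(self):
        # three points on a line with spacings 1 and 1 (ends 2 apart)
        D = DistanceMatrix(
            ["l", "m", "r"],
            np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
        )
        res = classical_mds(D, dims=1)
        axis = res.coordinates["axis1"]
        assert axis["m"] == pytest.approx((axis["l"] + axis["r"]) / 2, abs=1e-9)
        assert (axis["l"] < axis["m"] < axis["r"]) or (
            axis["l"] > axis["m"] > axis["r"]
        )

    def test_eigenvalues_decreasing(self, rng):
        m = random_matrix(rng, [f"s{i}" for i in range(8)], 30)
        res = classical_mds(pairwise_distances(m, "manhattan"), dims=4)
        assert all(a >= b for a, b in zip(res.eigenvalues, res.eigenvalues[1:]))

    def test_k_equals_n_saturates(self, rng):
        D, _ = _blob_distances(rng, sizes=(3, 3))
        _, part = reduce_and_partition(D, dims=2, K=6, seed=0)
        assert len(set(part.values())) == 6

    def test_more_dims_than_positive_axes_warns(self):
        # collinear points embed in one dimension; asking for two must warn
        # and return the single available axis
        D = DistanceMatrix(
            ["l", "m", "r"],
            np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
        )
        with pytest.warns(UserWarning, match="positive MDS axes"):
            res = classical_mds(D, dims=2)
        assert res.coordinates.shape[1] == 1


class TestDiagnostics:
    def test_three_groups_show_elbow_at_three(self, rng):
        D, _ = _blob_distances(rng, sizes=(4, 4, 4), separation=60)
        table = cluster_diagnostics(D, range(2, 7), seed=0, dims=2)
        wss = table.set_index("K")["wss"]
        drops = wss.shift(1) - wss
        assert drops.idxmax() == 3  # steepest drop arriving at K=3
        assert wss[3] < 0.05 * wss[2]

    def test_identical_points_have_zero_dispersion(self):
        n = 6
        D = DistanceMatrix([f"s{i}" for i in range(n)], np.zeros((n, n)))
        table = cluster_diagnostics(D, range(2, 5), seed=0)
        assert (table["wss"] == 0).all()

    def test_single_k_gives_one_row_without_ari(self, rng):
        D, _ = _blob_distances(rng)
        table = cluster_diagnostics(D, [4], seed=0, dims=2)
        assert len(table) == 1
        assert np.isnan(table["ari_with_prev"]).all()
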