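"""Scaling, fuzzy c-means, k selection and membership scoring."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import splicedyn.synthetic_data as sd
from splicedyn.temporal_clustering import (
    ClusterModel,
    fuzzy_cmeans,
    membership_to,
    min_centroid_distance,
    scale_profiles,
    select_k,
)


class TestScaleProfiles:
    def test_zscore_definition(self):
        out, dropped = scale_profiles(pd.DataFrame([[10.0, 20.0, 30.0]]))
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])
        assert dropped == []

    def test_rows_have_mean_zero_sd_one(self, rng):
        x = rng.uniform(0, 100, (30, 8))
        out, _ = scale_profiles(x)
        v = out.to_numpy()
        assert np.allclose(v.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(v.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotence(self, rng):
        x = rng.uniform(0, 100, (10, 6))
        once, _ = scale_profiles(x)
        twice, _ = scale_profiles(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_constant_rows_dropped_and_reported(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                         index=["ok", "flat"])
        out, dropped = scale_profiles(x)
        assert list(out.index) == ["ok"] and dropped == ["flat"]

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            scale_profiles(pd.DataFrame([[1.0, 1.0, 1.0]]))


def _manual_model(centroids: np.ndarray, m: float = 1.25) -> ClusterModel:
    k = centroids.shape[0]
    return ClusterModel(k=k, m=m, centroids=centroids,
                        memberships=np.full((1, k), 1.0 / k),
                        iterations=0, objective=0.0)


class TestFuzzyCMeans:
    def test_item_at_centroid_has_membership_one(self, rng):
        x = np.vstack([np.zeros((5, 4)) + [0, 0, 0, 0],
                       np.ones((5, 4)) * 3])
        x += np.vstack([np.zeros((1, 4)),
                        rng.normal(0, 0.01, (9, 4))])
        model = fuzzy_cmeans(x, k=2, seed=0)
        u = membership_to(x, model, include_negatives=False)
        at_centroid = np.vstack([model.centroids[0]])
        u0 = membership_to(at_centroid, model, include_negatives=False)
        assert u0.to_numpy().max() == pytest.approx(1.0)
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_equidistant_item_splits_membership(self):
        model = _manual_model(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        u = membership_to(np.array([[0.0, 5.0]]), model,
                          include_negatives=False)
        assert np.allclose(u.to_numpy(), [[0.5, 0.5]])

    def test_blob_partition_matches_exhaustive_oracle(self, rng):
        # 12 points, 2 separated blobs; oracle enumerates all 2-partitions
        # and minimizes the fuzzy objective evaluated at partition means
        pts = np.vstack([rng.normal(0, 0.4, (6, 3)),
                         rng.normal(4, 0.4, (6, 3))])
        model = fuzzy_cmeans(pts, k=2, m=1.25, seed=5)
        hard = model.hard_assignments()

        best = None
        for assign in product([0, 1], repeat=len(pts) - 1):
            lab = np.array((0,) + assign)
            if len(set(lab)) < 2:
                continue
            obj = 0.0
            for c in (0, 1):
                grp = pts[lab == c]
                obj += ((grp - grp.mean(axis=0)) ** 2).sum()
            if best is None or obj < best[0]:
                best = (obj, lab)
        assert adjusted_rand_score(best[1], hard) == 1.0

    def test_objective_monotone_and_memberships_normalized(self, rng):
        x = rng.normal(0, 1, (60, 5))
        model = fuzzy_cmeans(x, k=3, seed=2)
        trace = model.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        assert np.allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_k_must_be_below_n_items(self, rng):
        with pytest.raises(ValueError):
            fuzzy_cmeans(rng.normal(0, 1, (4, 3)), k=4, seed=0)

    def test_same_seed_reproduces_model(self, rng):
        x = rng.normal(0, 1, (40, 5))
        a = fuzzy_cmeans(x, k=3, seed=9)
        b = fuzzy_cmeans(x, k=3, seed=9)
        assert np.array_equal(a.centroids, b.centroids)

    def test_planted_clusters_recovered(self):
        x, labels = sd.simulate_scaled_trajectories(100, noise_sd=0.3,
                                                    seed=3)
        scaled, _ = scale_profiles(x)
        model = fuzzy_cmeans(scaled, k=6, m=1.25, seed=4, n_restarts=10)
        ari = adjusted_rand_score(labels.loc[scaled.index],
                                  model.hard_assignments())
        assert ari >= 0.8


class TestSelectK:
    def test_planted_k_recovered(self):
        x, _ = sd.simulate_scaled_trajectories(60, noise_sd=0.2, seed=6)
        scaled, _ = scale_profiles(x)
        k, curve = select_k(scaled, list(range(2, 10)), seed=7)
        assert len(curve) == 8
        assert k == 6

    def test_single_candidate_returned(self, rng):
        x = rng.normal(0, 1, (20, 4))
        k, curve = select_k(x, [2], seed=0)
        assert k == 2 and len(curve) == 1

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(0, 1, (20, 4)), [], seed=0)


class TestMembershipTo:
    def test_centroid_maps_to_positive_slot(self):
        c = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]])
        model = _manual_model(c)
        u = membership_to(c[[0]], model)
        assert u.columns[u.to_numpy().argmax()] == "pos_0"

    def test_negated_centroid_maps_to_negative_slot(self):
        c = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]])
        model = _manual_model(c)
        u = membership_to(-c[[1]], model)
        assert u.columns[u.to_numpy().argmax()] == "neg_1"

    def test_rows_sum_to_one(self, rng):
        c = rng.normal(0, 1, (4, 6))
        model = _manual_model(c)
        u = membership_to(rng.normal(0, 1, (50, 6)), model)
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = _manual_model(rng.normal(0, 1, (2, 5)))
        with pytest.raises(ValueError, match="length"):
            membership_to(rng.normal(0, 1, (3, 4)), model)

    def test_unrelated_profiles_rarely_reach_threshold(self, rng):
        """Random profiles spread membership below the 0.3 call cutoff."""
        specs = sd.default_trajectory_specs()
        centroids = sd.cluster_centroid_profiles(specs)
        model = _manual_model(centroids, m=1.25)
        noise = rng.normal(0, 1, (300, centroids.shape[1]))
        noise, _ = scale_profiles(noise)
        u = membership_to(noise, model, m=2.0)
        assert (u.to_numpy().max(axis=1) >= 0.3).mean() < 0.05

    def test_null_mean_membership_near_uniform(self, rng):
        """Mean membership of nulls approaches 1/(2k) across the slots."""
        specs = sd.default_trajectory_specs()
        model = _manual_model(sd.cluster_centroid_profiles(specs))
        noise, _ = scale_profiles(rng.normal(0, 1, (500, model.centroids.shape[1])))
        u = membership_to(noise, model, m=2.0)
        assert u.to_numpy().mean(axis=0) == pytest.approx(
            np.full(2 * model.k, 1 / (2 * model.k)), abs=0.03)


def test_min_centroid_distance_is_smallest_pair():
    model = _manual_model(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 1.0]]))
    assert min_centroid_distance(model) == pytest.approx(1.0)
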