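"""Community dissimilarities, NMDS, environmental fitting and concordance."""

import numpy as np
import pandas as pd
import pytest

from birdscape import ordination as o
from birdscape.ordination import OrdinationError


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert o.bray_curtis(X, log1p=False)[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        X = np.array([[5.0, 0.0], [0.0, 7.0]])
        assert o.bray_curtis(X, log1p=False)[0, 1] == 1.0

    def test_direct_evaluation(self):
        X = np.array([[2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        assert o.bray_curtis(X, log1p=False)[0, 1] == pytest.approx(0.6)

    def test_log1p_applied_before_distance(self):
        X = np.array([[np.e - 1, 0.0], [0.0, np.e - 1]])
        # after log1p both rows are (1,0)/(0,1): still disjoint
        assert o.bray_curtis(X, log1p=True)[0, 1] == 1.0

    def test_all_zero_row_rejected(self):
        with pytest.raises(OrdinationError, match="all-zero"):
            o.bray_curtis(np.array([[0.0, 0.0], [1.0, 2.0]]))

    def test_symmetric_bounded(self, rng):
        X = rng.uniform(0, 10, (12, 8))
        D = o.bray_curtis(X)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        assert D.min() >= 0 and D.max() <= 1


class TestJaccard:
    def test_identical_zero(self):
        Xb = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
        assert o.jaccard(Xb)[0, 1] == 0.0

    def test_direct_evaluation(self):
        Xb = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        assert o.jaccard(Xb)[0, 1] == pytest.approx(2 / 3)

    def test_jaccard_bray_curtis_identity_on_binary(self, rng):
        Xb = (rng.random((10, 15)) < 0.4).astype(float)
        Xb[Xb.sum(axis=1) == 0, 0] = 1.0
        J = o.jaccard(Xb)
        BC = o.bray_curtis(Xb, log1p=False)
        assert np.allclose(J, 2 * BC / (1 + BC))

    def test_non_binary_rejected(self):
        with pytest.raises(OrdinationError):
            o.jaccard(np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_presence_absence_conversion(self):
        X = pd.DataFrame([[0.0, 3.2], [0.1, 0.0]])
        Xb = o.to_presence_absence(X)
        assert Xb.values.tolist() == [[0.0, 1.0], [1.0, 0.0]]


class TestNmds:
    def euclidean_points(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        P = rng.normal(0, 1, (n, 2))
        D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
        return P, D

    def test_embeddable_distances_reach_near_zero_stress(self):
        _, D = self.euclidean_points()
        res = o.nmds(D, n_starts=5, seed=1)
        assert res.stress < 0.01

    def test_tetrahedron_cannot_embed_in_2d(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(OrdinationError):
            o.nmds(D, k=3)  # k must be < n-1
        res = o.nmds(D, k=2, n_starts=10, seed=0)
        assert res.stress > 0.0

    def test_seed_reproducibility(self):
        _, D = self.euclidean_points(seed=3)
        a = o.nmds(D, n_starts=4, seed=7)
        b = o.nmds(D, n_starts=4, seed=7)
        assert np.array_equal(a.scores, b.scores) and a.stress == b.stress

    def test_stress_monotone_within_start(self, rng):
        X = rng.uniform(0, 5, (15, 6))
        D = o.bray_curtis(X, log1p=False)
        res = o.nmds(D, n_starts=3, seed=2)
        trace = np.asarray(res.stress_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_higher_k_never_worse(self, rng):
        X = rng.uniform(0, 5, (15, 6))
        D = o.bray_curtis(X, log1p=False)
        s2 = o.nmds(D, k=2, n_starts=8, seed=4).stress
        s3 = o.nmds(D, k=3, n_starts=8, seed=4).stress
        assert s3 <= s2 + 1e-6

    def test_scores_centred(self):
        _, D = self.euclidean_points(seed=5)
        res = o.nmds(D, n_starts=3, seed=5)
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-8)

    def test_invalid_distance_matrix_rejected(self):
        with pytest.raises(OrdinationError):
            o.nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestRotateToVariable:
    def ordination(self, seed=0):
        rng = np.random.default_rng(seed)
        P = rng.normal(0, 1, (25, 2))
        D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
        return o.nmds(D, n_starts=3, seed=seed)

    def test_aligned_variable_identity_up_to_sign(self):
        res = self.ordination()
        v = res.scores[:, 0].copy()
        rot = o.rotate_to_variable(res, v)
        assert np.allclose(np.abs(rot.scores), np.abs(res.scores), atol=1e-6)

    def test_rigid_rotation_preserves_distances(self):
        res = self.ordination(seed=1)
        v = res.scores @ np.array([0.6, 0.8])
        rot = o.rotate_to_variable(res, v)
        d0 = np.sqrt(((res.scores[:, None] - res.scores[None, :]) ** 2).sum(-1))
        d1 = np.sqrt(((rot.scores[:, None] - rot.scores[None, :]) ** 2).sum(-1))
        assert np.allclose(d0, d1, atol=1e-10)
        assert rot.stress == res.stress

    def test_post_rotation_direction_is_axis_one(self):
        res = self.ordination(seed=2)
        rng = np.random.default_rng(3)
        v = res.scores @ np.array([0.3, -0.9]) + rng.normal(0, 0.05, 25)
        rot = o.rotate_to_variable(res, v)
        direction, _ = o._envfit_vector(rot.scores, v)
        assert np.allclose(direction, [1.0, 0.0], atol=1e-6)

    def test_zero_variance_rejected(self):
        res = self.ordination(seed=4)
        with pytest.raises(OrdinationError):
            o.rotate_to_variable(res, np.ones(25))


class TestEnvfit:
    def ordination(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        P = rng.normal(0, 1, (n, 2))
        D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
        return o.nmds(D, n_starts=3, seed=seed)

    def test_variable_equal_to_axis_one(self):
        res = self.ordination()
        env = pd.DataFrame({"v": res.scores[:, 0]})
        ef = o.envfit(res, env, n_perm=99, seed=1)
        row = ef.vectors.loc["v"]
        assert row["r2"] == pytest.approx(1.0, abs=1e-10)
        assert abs(row["dir1"]) == pytest.approx(1.0, abs=1e-6)

    def test_noise_variable_rarely_significant(self):
        res = self.ordination(seed=2, n=40)
        rng = np.random.default_rng(5)
        sig = 0
        for _ in range(10):
            env = pd.DataFrame({"v": rng.normal(0, 1, 40)})
            ef = o.envfit(res, env, n_perm=99, seed=int(rng.integers(2**31)))
            if ef.vectors.loc["v", "p"] <= 0.05:
                sig += 1
        assert sig <= 2

    def test_perfectly_partitioned_factor(self):
        rng = np.random.default_rng(7)
        centres = np.array([[-5.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        labels = np.repeat(["a", "b", "c"], 12)
        P = centres[np.repeat(np.arange(3), 12)] + rng.normal(0, 0.1, (36, 2))
        D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
        res = o.nmds(D, n_starts=3, seed=0)
        ef = o.envfit(res, pd.DataFrame({"f": labels}), n_perm=999, seed=1)
        assert ef.factors["f"]["r2"] > 0.95
        assert ef.factors["f"]["p"] <= 0.001

    def test_constant_variable_warns(self):
        res = self.ordination(seed=3)
        with pytest.warns(UserWarning, match="constant"):
            ef = o.envfit(res, pd.DataFrame({"v": np.ones(30)}), n_perm=9)
        assert ef.vectors.loc["v", "r2"] == 0.0 and ef.vectors.loc["v", "p"] == 1.0


class TestAssignHabitat:
    def traits(self, pairs):
        return pd.DataFrame(pairs, columns=["species", "habitat"])

    def test_rock_reassigned_to_human_modified(self):
        out = o.assign_habitat(self.traits([("sp1", "Rock")]))
        assert out["sp1"] == "human-modified"

    def test_coastal_reassigned_inland(self):
        out = o.assign_habitat(self.traits([("sp1", "Coastal")]))
        assert out["sp1"] == "human-modified"

    def test_forest_passes_through(self):
        out = o.assign_habitat(self.traits([("sp1", "Forest")]))
        assert out["sp1"] == "forest"

    def test_water_classes_pooled(self):
        out = o.assign_habitat(self.traits([("a", "Riverine"), ("b", "Wetland")]))
        assert out["a"] == out["b"] == "aquatic"

    def test_open_classes_pooled(self):
        out = o.assign_habitat(self.traits([("a", "Grassland"), ("b", "Shrubland")]))
        assert out["a"] == out["b"] == "open"

    def test_missing_species_listed(self):
        with pytest.raises(OrdinationError, match="sp2"):
            o.assign_habitat(self.traits([("sp1", "Forest")]), species=["sp1", "sp2"])

    def test_unknown_label_rejected(self):
        with pytest.raises(OrdinationError, match="unknown"):
            o.assign_habitat(self.traits([("sp1", "Volcanic")]))


class TestProcrustes:
    def test_similarity_transform_recovered(self, rng):
        A = rng.normal(0, 1, (20, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        B = 3.0 * A @ R @ np.diag([1, -1]) + np.array([5.0, -2.0])
        m2, t, p = o.procrustes_protest(A, B, n_perm=99, seed=0)
        assert m2 < 1e-10
        assert t == pytest.approx(1.0, abs=1e-6)
        assert p <= 0.01

    def test_t_m2_identity(self, rng):
        A = rng.normal(0, 1, (15, 2))
        B = rng.normal(0, 1, (15, 2))
        m2, t, _ = o.procrustes_protest(A, B, n_perm=9, seed=1)
        assert t**2 == pytest.approx(1 - m2, abs=1e-12)

    def test_independent_scores_not_significant(self):
        rng = np.random.default_rng(11)
        sig = 0
        for _ in range(10):
            A = rng.normal(0, 1, (30, 2))
            B = rng.normal(0, 1, (30, 2))
            _, _, p = o.procrustes_protest(A, B, n_perm=99, seed=int(rng.integers(2**31)))
            if p <= 0.05:
                sig += 1
        assert sig <= 2


class TestMantel:
    def dist(self, n, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(0, 1, (n, 3))
        return np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))

    def test_self_correlation_is_one(self):
        D = self.dist(15, 0)
        r, _ = o.mantel(D, D, n_perm=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_lower_triangle_r_matches_loop_oracle(self):
        D1, D2 = self.dist(12, 1), self.dist(12, 2)
        r, _ = o.mantel(D1, D2, n_perm=9, seed=0)
        a = [D1[i, j] for i in range(12) for j in range(i)]
        b = [D2[i, j] for i in range(12) for j in range(i)]
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(OrdinationError):
            o.mantel(self.dist(10, 0), self.dist(11, 0))

    def test_related_matrices_significant(self):
        rng = np.random.default_rng(3)
        P = rng.normal(0, 1, (25, 2))
        D1 = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
        D2 = D1 + rng.uniform(0, 0.1, D1.shape)
        D2 = (D2 + D2.T) / 2
        np.fill_diagonal(D2, 0)
        r, p = o.mantel(D1, D2, n_perm=199, seed=4)
        assert r > 0.9 and p < 0.05


def test_structural_recovery_on_niche_gradient(small_sites, small_detections):
    """With a strong NDVI niche gradient, envfit must score NDVI far above
    noise, and the VAR and presence-absence ordinations must agree."""
    from birdscape import acoustic

    pool, ndvi_at, dets = small_detections
    dets = acoustic.remove_singletons(acoustic.filter_confidence(dets))
    vt = acoustic.var_per_species(dets, small_sites[["site_id", "days_recorded"]])
    comm = vt.pivot_table(index="site_id", columns="species", values="var", fill_value=0.0)
    idx = {s: i for i, s in enumerate(small_sites["site_id"])}
    ndvi_v = np.array([ndvi_at[idx[s]] for s in comm.index])
    D = o.bray_curtis(comm)
    res = o.nmds(D, n_starts=8, seed=0)
    rng = np.random.default_rng(1)
    env = pd.DataFrame({"ndvi": ndvi_v, "noise": rng.normal(0, 1, len(ndvi_v))})
    ef = o.envfit(res, env, n_perm=199, seed=2)
    assert ef.vectors.loc["ndvi", "r2"] > ef.vectors.loc["noise", "r2"]
    Dj = o.jaccard(o.to_presence_absence(comm))
    r, _ = o.mantel(D, Dj, n_perm=99, seed=3)
    assert r > 0.5
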