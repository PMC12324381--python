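"""DBSCAN, silhouette and parameter-selection behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bristlekit.cluster import (
    OUTLIER,
    ROLE_BOUNDARY,
    ROLE_CORE,
    ROLE_OUTLIER,
    ClusteringParams,
    SilhouetteTunedDBSCAN,
    dbscan,
    default_eps_grid,
    optimize_params,
    pattern_silhouette,
    silhouette,
)

from _oracles import brute_dbscan, direct_silhouette
from conftest import LINE_TWO_CLUSTERS, TWO_SQUARES


class TestDBSCAN:
    def test_single_point_below_minpts_is_outlier(self):
        lab = dbscan(np.array([[0.0, 0.0]]), ClusteringParams(1.0, 2))
        assert lab.k == 0
        assert lab.labels.tolist() == [OUTLIER]
        assert lab.roles.tolist() == [ROLE_OUTLIER]

    def test_collinear_chain_single_cluster_with_boundary_ends(self):
        pts = np.array([[x, 0.0] for x in range(5)], dtype=float)
        lab = dbscan(pts, ClusteringParams(1.5, 3))
        assert lab.k == 1
        assert lab.labels.tolist() == [0] * 5
        # interior points see 3 neighbours (self included), ends only 2
        assert lab.roles.tolist() == [
            ROLE_BOUNDARY, ROLE_CORE, ROLE_CORE, ROLE_CORE, ROLE_BOUNDARY,
        ]

    def test_two_separated_squares_form_two_all_core_clusters(self):
        lab = dbscan(TWO_SQUARES, ClusteringParams(1.5, 4))
        assert lab.k == 2
        assert lab.labels.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]
        assert (lab.roles == ROLE_CORE).all()
        assert lab.n_outliers == 0

    def test_empty_input_gives_empty_labeling(self):
        lab = dbscan(np.empty((0, 2)), ClusteringParams(1.0, 2))
        assert lab.k == 0 and lab.labels.size == 0

    def test_minpts_one_makes_every_point_core(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0]])
        lab = dbscan(pts, ClusteringParams(1.0, 1))
        assert (lab.roles == ROLE_CORE).all()
        assert lab.k == 2

    def test_duplicate_coordinates_tolerated(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        lab = dbscan(pts, ClusteringParams(0.5, 3))
        assert lab.k == 1 and (lab.roles == ROLE_CORE).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClusteringParams(0.0, 3)
        with pytest.raises(ValueError):
            ClusteringParams(1.0, 0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle_on_random_patterns(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        pts = rng.uniform(0, 10, size=(n, 2))
        nn = np.sort(
            np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) + np.eye(n) * 1e9,
            axis=1,
        )[:, 0]
        eps = float(rng.uniform(0.5, 3.0) * np.median(nn))
        min_pts = int(rng.integers(2, 7))
        core, outliers, partition, labels = brute_dbscan(pts, eps, min_pts)
        lab = dbscan(pts, ClusteringParams(eps, min_pts))
        assert set(np.flatnonzero(lab.roles == ROLE_CORE)) == core
        assert set(np.flatnonzero(lab.labels == OUTLIER)) == outliers
        assert lab.labels.tolist() == labels

    def test_permutation_equivariance_of_roles_and_core_partition(self, rng):
        pts = rng.uniform(0, 10, size=(40, 2))
        params = ClusteringParams(1.2, 3)
        lab = dbscan(pts, params)
        perm = rng.permutation(40)
        lab_p = dbscan(pts[perm], params)
        assert (lab_p.roles == lab.roles[perm]).all()
        # core partition is permutation-invariant as a set of sets
        def core_partition(labels, roles, order):
            out = {}
            for pos, orig in enumerate(order):
                if roles[pos] == ROLE_CORE:
                    out.setdefault(labels[pos], set()).add(orig)
            return {frozenset(v) for v in out.values()}

        assert core_partition(lab.labels, lab.roles, range(40)) == core_partition(
            lab_p.labels, lab_p.roles, perm
        )

    @given(eps_pair=st.tuples(st.floats(0.2, 5.0), st.floats(0.2, 5.0)), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_outlier_count_nonincreasing_in_eps(self, eps_pair, seed):
        pts = np.random.default_rng(seed).uniform(0, 10, size=(30, 2))
        lo, hi = sorted(eps_pair)
        out_lo = dbscan(pts, ClusteringParams(lo, 3)).n_outliers
        out_hi = dbscan(pts, ClusteringParams(hi, 3)).n_outliers
        assert out_hi <= out_lo

    def test_boundary_points_within_eps_of_their_cluster_core(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 8, size=(35, 2))
            eps = 1.0
            lab = dbscan(pts, ClusteringParams(eps, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            for i in np.flatnonzero(lab.roles == ROLE_BOUNDARY):
                same = (lab.labels == lab.labels[i]) & (lab.roles == ROLE_CORE)
                assert d[i, same].min() <= eps

    def test_agrees_with_sklearn_on_core_and_outlier_sets(self, rng):
        # independent cross-check: sklearn's DBSCAN shares the core/noise
        # definition even though its boundary tie-break differs
        from sklearn.cluster import DBSCAN as SkDBSCAN

        for _ in range(10):
            pts = rng.uniform(0, 10, size=(45, 2))
            eps, mp = 1.3, 4
            sk = SkDBSCAN(eps=eps, min_samples=mp).fit(pts)
            lab = dbscan(pts, ClusteringParams(eps, mp))
            assert set(sk.core_sample_indices_) == set(
                np.flatnonzero(lab.roles == ROLE_CORE)
            )
            # outliers can differ only for boundary points; sklearn noise
            # is exactly our outlier set
            assert set(np.flatnonzero(sk.labels_ == -1)) == set(
                np.flatnonzero(lab.labels == OUTLIER)
            )


class TestSilhouette:
    def test_line_example_matches_direct_formula(self):
        lab = dbscan(LINE_TWO_CLUSTERS, ClusteringParams(1.5, 2))
        assert lab.k == 2
        br = silhouette(LINE_TWO_CLUSTERS, lab)
        # outer points: a=1, b=10.5; inner points: a=1, b=9.5
        np.testing.assert_allclose(br.s[0], 9.5 / 10.5, atol=1e-12)
        np.testing.assert_allclose(br.s[3], 9.5 / 10.5, atol=1e-12)
        np.testing.assert_allclose(br.s[1], 8.5 / 9.5, atol=1e-12)
        np.testing.assert_allclose(br.s[2], 8.5 / 9.5, atol=1e-12)
        assert br.valid.all()

    def test_single_cluster_invalidates_all_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        lab = dbscan(pts, ClusteringParams(1.5, 2))
        assert lab.k == 1
        br = silhouette(pts, lab)
        assert not br.valid.any()
        assert (br.s == 0).all()
        assert np.isnan(pattern_silhouette(br))

    def test_duplicate_point_in_two_point_cluster_scores_one(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [50.0, 0.0], [50.0, 1.0]])
        lab = dbscan(pts, ClusteringParams(1.5, 2))
        br = silhouette(pts, lab)
        assert br.a[0] == 0 and br.b[0] > 0
        np.testing.assert_allclose(br.s[0], 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_evaluation_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        pts = rng.uniform(0, 10, size=(n, 2))
        labels = rng.integers(-1, 4, size=n)
        from bristlekit.cluster import ClusterLabeling

        k = int(labels.max()) + 1 if (labels >= 0).any() else 0
        # normalise to contiguous ids as the contract requires
        ids = sorted(set(labels[labels >= 0]))
        remap = {c: i for i, c in enumerate(ids)}
        labels = np.array([remap.get(c, OUTLIER) for c in labels])
        k = len(ids)
        roles = np.where(labels == OUTLIER, ROLE_OUTLIER, ROLE_CORE)
        lab = ClusterLabeling(labels, roles, k, ClusteringParams(1.0, 1))
        br = silhouette(pts, lab)
        np.testing.assert_allclose(br.s, direct_silhouette(pts, labels), atol=1e-12)

    def test_sklearn_cross_check_on_clean_two_cluster_labeling(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(8, 1, (15, 2))])
        labels = np.array([0] * 15 + [1] * 15)
        from bristlekit.cluster import ClusterLabeling

        lab = ClusterLabeling(
            labels, np.full(30, ROLE_CORE), 2, ClusteringParams(1.0, 1)
        )
        br = silhouette(pts, lab)
        np.testing.assert_allclose(
            br.s, silhouette_samples(pts, labels), atol=1e-10
        )

    def test_zero_mode_counts_all_points(self):
        lab = dbscan(TWO_SQUARES, ClusteringParams(1.5, 4))
        br = silhouette(TWO_SQUARES, lab)
        assert pattern_silhouette(br, cq_outliers="zero") == pytest.approx(
            br.s.mean()
        )
        assert pattern_silhouette(br, cq_outliers="exclude") == pytest.approx(
            br.s[br.valid].mean()
        )


class TestParameterSelection:
    def test_single_candidate_grid_returned_as_is(self):
        params, lab, cq = optimize_params(TWO_SQUARES, [1.5], [4])
        assert params.eps == 1.5 and params.min_pts == 4
        assert lab.k == 2
        assert cq > 0.9

    def test_separating_eps_beats_merging_eps(self):
        # eps=200 merges the squares into one cluster (invalid, K=1)
        params, lab, cq = optimize_params(TWO_SQUARES, [1.5, 200.0], [4])
        assert params.eps == 1.5
        assert lab.k == 2

    def test_grid_order_irrelevant(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 20, size=(40, 2))
        eps_grid = [1.0, 2.5, 5.0, 10.0]
        a = optimize_params(pts, eps_grid, [3, 4])
        b = optimize_params(pts, eps_grid[::-1], [4, 3])
        assert a[0] == b[0]
        assert a[2] == b[2]

    def test_all_invalid_returns_largest_k_with_missing_cq(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
        params, lab, cq = optimize_params(pts, [1.0], [3])
        assert np.isnan(cq)
        assert lab.k == 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimize_params(TWO_SQUARES, [], [3])

    def test_estimator_api_roundtrip(self):
        est = SilhouetteTunedDBSCAN(eps_grid=[1.5], min_pts_grid=[4])
        assert est.get_params()["eps_grid"] == [1.5]
        est.set_params(min_pts_grid=[3, 4])
        labels = est.fit_predict(TWO_SQUARES)
        assert est.n_clusters_ == 2
        assert labels.shape == (8,)

    def test_default_eps_grid_tracks_pattern_scale(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, size=(50, 2))
        g1 = default_eps_grid(pts)
        g10 = default_eps_grid(pts * 10)
        assert len(g1) == 15
        np.testing.assert_allclose(g10, g1 * 10, rtol=1e-9)
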