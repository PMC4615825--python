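import numpy as np
import pytest
from scipy import ndimage

from mcthick import (FuzzyCMeans, build_nested_labels, fcm_segment,
                     keep_largest_component, smooth_inner_boundary,
                     strip_pial_voxels)
from mcthick.segmentation import (LBL_GM, LBL_MGM, LBL_WM, MembershipSet,
                                  NestedLabels, fcm_objective)


class TestFuzzyCMeans:
    def test_noiseless_phantom_recovers_exact_centroids(self, noiseless_phantom):
        _, ratio, truth = noiseless_phantom
        mem = fcm_segment(ratio, truth.mask, beta=0.0)
        np.testing.assert_allclose(mem.centroids, [1.0, 2.0, 3.0], atol=1e-6)
        # voxels sitting exactly at a centroid get a one-hot membership
        m = truth.mask.bool_data
        for k, c in enumerate(mem.centroids):
            at_c = m & np.isclose(ratio.data, c)
            assert np.all(mem.memberships[at_c, k] > 1 - 1e-9)

    def test_six_voxel_instance_matches_brute_force_minimum(self):
        # independent minimization of the objective over memberships and
        # centroids (many random restarts) finds J* = 0 with centroids
        # {1, 2, 3} and one-hot memberships; frozen here
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0]).reshape(6, 1, 1)
        mask = np.ones((6, 1, 1), dtype=bool)
        mem = FuzzyCMeans(q=2.0, beta=0.0, tol=1e-14, max_iter=500).fit(y, mask)
        np.testing.assert_allclose(mem.centroids, [1.0, 2.0, 3.0], atol=1e-9)
        expected_u = np.repeat(np.eye(3), 2, axis=0)
        np.testing.assert_allclose(mem.memberships.reshape(6, 3), expected_u,
                                   atol=1e-9)
        assert mem.objective_trace[-1] <= 1e-8

    def test_constant_image_is_degenerate(self):
        y = np.full((5, 5, 5), 2.0)
        with pytest.raises(ValueError, match="distinct"):
            FuzzyCMeans().fit(y, np.ones((5, 5, 5), bool))

    def test_memberships_sum_to_one_and_objective_monotone(self, noisy_phantom):
        _, ratio, truth = noisy_phantom
        for beta in (0.0, 0.5):
            mem = fcm_segment(ratio, truth.mask, beta=beta)
            m = truth.mask.bool_data
            sums = mem.memberships.sum(axis=-1)
            np.testing.assert_allclose(sums[m], 1.0, atol=1e-6)
            np.testing.assert_array_equal(mem.memberships[~m], 0.0)
            assert np.all((mem.memberships >= 0) & (mem.memberships <= 1))
            trace = np.asarray(mem.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]))

    def test_trace_matches_objective_function(self, noisy_phantom):
        _, ratio, truth = noisy_phantom
        mem = fcm_segment(ratio, truth.mask, beta=0.3)
        j = fcm_objective(ratio.data.astype(float), mem.memberships,
                          mem.centroids, 2.0, 0.3, truth.mask.bool_data)
        np.testing.assert_allclose(j, mem.objective_trace[-1], rtol=1e-9)

    def test_initial_centroid_order_does_not_matter(self, noisy_phantom):
        _, ratio, truth = noisy_phantom
        model = FuzzyCMeans()
        a = model.fit(ratio.data, truth.mask.bool_data,
                      init_centroids=[1.0, 2.0, 3.0])
        b = model.fit(ratio.data, truth.mask.bool_data,
                      init_centroids=[3.0, 1.0, 2.0])
        np.testing.assert_array_equal(a.centroids, b.centroids)
        np.testing.assert_array_equal(a.memberships, b.memberships)

    def test_spatial_weight_removes_isolated_salt_errors(self, noiseless_phantom):
        _, ratio, truth = noiseless_phantom
        rng = np.random.default_rng(42)
        img = ratio.data.copy()
        m = truth.mask.bool_data
        idx = np.argwhere(m)
        salt = idx[rng.choice(len(idx), size=int(0.03 * len(idx)), replace=False)]
        c = np.array([1.0, 2.0, 3.0])
        for i, j, k in salt:
            img[i, j, k] = rng.choice(c[c != img[i, j, k]])
        noisy = ratio.with_data(img)

        def isolated_errors(beta):
            mem = fcm_segment(noisy, truth.mask, beta=beta)
            lab = build_nested_labels(mem)
            wrong = (lab.labels != truth.labels) & m
            comp, _ = ndimage.label(wrong, structure=np.ones((3, 3, 3)))
            sizes = np.bincount(comp.ravel())[1:]
            return int((sizes == 1).sum())

        assert isolated_errors(0.5) < isolated_errors(0.0)


class TestNestedLabels:
    def _membership_set(self, u_rows, mask=None):
        n = len(u_rows)
        u = np.asarray(u_rows, dtype=float).reshape(n, 1, 1, 3)
        mask = np.ones((n, 1, 1), bool) if mask is None else mask
        return MembershipSet(memberships=u, centroids=np.array([1.0, 2.0, 3.0]),
                             mask=mask, affine=np.eye(4))

    @pytest.mark.parametrize("u,expected", [
        ((0.00, 0.85, 0.15), LBL_WM),    # u_WM above the refined 0.1 threshold
        ((0.35, 0.55, 0.10), LBL_MGM),   # strict: 0.10 is not > 0.1
        ((1.0, 0.0, 0.0), LBL_GM),
        ((0.5, 0.4, 0.1), 0),            # passes no strict threshold: background
    ])
    def test_sequential_threshold_semantics(self, u, expected):
        m = self._membership_set([u])
        labels = build_nested_labels(m)
        assert labels.labels[0, 0, 0] == expected

    def test_thresholds_outside_unit_interval_rejected(self):
        m = self._membership_set([(1.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            build_nested_labels(m, wm_threshold=0.0)
        with pytest.raises(ValueError):
            build_nested_labels(m, gm_threshold=1.0)

    def test_wm_threshold_change_leaves_inner_boundary_fixed(self, noisy_phantom):
        _, ratio, truth = noisy_phantom
        mem = fcm_segment(ratio, truth.mask)
        loose = build_nested_labels(mem, wm_threshold=0.1)
        tight = build_nested_labels(mem, wm_threshold=0.5)
        np.testing.assert_array_equal(loose.r_inner, tight.r_inner)
        np.testing.assert_array_equal(loose.r_cortex, tight.r_cortex)

    def test_noiseless_labels_reproduce_generating_classes(self, noiseless_phantom):
        _, ratio, truth = noiseless_phantom
        mem = fcm_segment(ratio, truth.mask, beta=0.0)
        labels = build_nested_labels(mem)
        np.testing.assert_array_equal(labels.labels, truth.labels)


def _two_blob_labels(sizes=(100, 3)):
    labels = np.zeros((20, 20, 20), dtype=np.int8)
    labels[2:18, 2:18, 2:18] = LBL_MGM
    labels[3:8, 3:8, 3:7] = LBL_WM            # 5*5*4 = 100 voxels
    labels[12:15, 12:13, 12:13] = LBL_WM      # 3 voxels, disjoint
    out = NestedLabels(labels, np.eye(4))
    assert out.r_wm.sum() == sum(sizes)
    return out


class TestMorphology:
    def test_largest_component_kept_smaller_demoted_to_mgm(self):
        labels = _two_blob_labels()
        out = keep_largest_component(labels)
        assert out.r_wm.sum() == 100
        assert out.labels[12, 12, 12] == LBL_MGM
        out.check_nesting()

    def test_single_component_unchanged(self):
        labels = _two_blob_labels()
        labels.labels[labels.labels == LBL_WM] = LBL_MGM
        labels.labels[3:8, 3:8, 3:7] = LBL_WM
        out = keep_largest_component(labels)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_equal_size_tie_keeps_lexicographically_first(self):
        labels = np.zeros((12, 12, 12), dtype=np.int8)
        labels[1:11, 1:11, 1:11] = LBL_MGM
        labels[2:4, 2:4, 2:4] = LBL_WM    # first in raster order
        labels[7:9, 7:9, 7:9] = LBL_WM    # equal size
        out = keep_largest_component(NestedLabels(labels, np.eye(4)))
        assert out.labels[2, 2, 2] == LBL_WM
        assert out.labels[7, 7, 7] == LBL_MGM

    def test_empty_wm_rejected(self):
        labels = np.zeros((6, 6, 6), dtype=np.int8)
        labels[1:5, 1:5, 1:5] = LBL_GM
        with pytest.raises(ValueError):
            keep_largest_component(NestedLabels(labels, np.eye(4)))

    def test_smoothing_removes_isolated_inner_voxel_keeps_wm(self, sphere_labels):
        labels = sphere_labels.copy()
        # an isolated mGM voxel in the GM shell, clear of the inner ball,
        # is a sub-kernel feature that opening removes
        labels.labels[24, 24, 33] = LBL_MGM
        out = smooth_inner_boundary(labels, kernel_mm=2.0)
        assert out.labels[24, 24, 33] == LBL_GM
        np.testing.assert_array_equal(out.r_wm, labels.r_wm)
        out.check_nesting()

    def test_smoothing_shifts_large_ball_boundary_at_most_one_voxel(self, sphere_labels):
        out = smooth_inner_boundary(sphere_labels, kernel_mm=2.0)
        changed = out.r_inner ^ sphere_labels.r_inner
        # changes confined to the immediate boundary shell of the inner region
        boundary = sphere_labels.r_inner ^ ndimage.binary_erosion(sphere_labels.r_inner)
        dilated_boundary = ndimage.binary_dilation(boundary, iterations=1)
        assert not (changed & ~dilated_boundary).any()

    def test_strip_pial_demotes_shell_inner_voxels(self):
        labels = np.zeros((10, 10, 10), dtype=np.int8)
        labels[1:9, 1:9, 1:9] = LBL_GM
        labels[3:7, 3:7, 3:7] = LBL_MGM
        labels[4:6, 4:6, 4:6] = LBL_WM
        labels[1, 4, 4] = LBL_MGM          # on the outer cortical shell
        out = strip_pial_voxels(NestedLabels(labels, np.eye(4)))
        assert out.labels[1, 4, 4] == LBL_GM
        # interior inner voxels untouched
        assert out.labels[4, 4, 4] == LBL_WM
        out.check_nesting()

    def test_strip_pial_on_slab_confines_inner_to_central_planes(self):
        # 10-plane cortex slab: after 1-voxel 6-connectivity erosion of the
        # cortex, inner tissue can only survive in the central 8 planes
        labels = np.zeros((12, 12, 12), dtype=np.int8)
        labels[1:11, 1:11, 1:11] = LBL_MGM   # inner tissue everywhere in cortex
        out = strip_pial_voxels(NestedLabels(labels, np.eye(4)))
        inner_planes = np.unique(np.argwhere(out.r_inner), axis=0)
        assert out.r_inner[2:10, 2:10, 2:10].all()
        assert not out.r_inner[1, :, :].any() and not out.r_inner[10, :, :].any()

    def test_nesting_preserved_through_full_cleanup(self, noisy_phantom):
        _, ratio, truth = noisy_phantom
        mem = fcm_segment(ratio, truth.mask)
        labels = build_nested_labels(mem)
        for op in (keep_largest_component,
                   lambda l: smooth_inner_boundary(l, 2.0),
                   strip_pial_voxels):
            labels = op(labels)
            labels.check_nesting()
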