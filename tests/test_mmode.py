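"""FCM clustering, morphological refinement and depth tracking."""

import numpy as np
import pytest

from opusmon.records import MModeImage, LesionMask
from opusmon.mmode import (
    FCMParams,
    build_mmode_image,
    depth_trace,
    fcm_cluster,
    refine_mask,
)


def make_image(pixels, pitch_mm=0.01, dt_s=0.1, laser_on=2, laser_off=8):
    pixels = np.asarray(pixels, float)
    return MModeImage(
        pixels=pixels,
        depth_axis_mm=np.arange(pixels.shape[0]) * pitch_mm,
        time_axis_s=np.arange(pixels.shape[1]) * dt_s,
        laser_on_index=laser_on,
        laser_off_index=laser_off,
        dynamic_range_db=40.0,
    )


def brute_force_fcm(x, c, m, seed, n_iter=500):
    """Independent loop-based FCM used as a restart oracle."""
    rng = np.random.default_rng(seed)
    n = x.size
    u = rng.random((n, c))
    u = u / u.sum(axis=1)[:, None]
    cost = np.inf
    for _ in range(n_iter):
        um = u ** m
        v = np.array([np.sum(um[:, j] * x) / np.sum(um[:, j]) for j in range(c)])
        d2 = np.array([[(x[i] - v[j]) ** 2 for j in range(c)] for i in range(n)])
        u_new = np.zeros_like(u)
        for i in range(n):
            if np.any(d2[i] == 0):
                u_new[i, np.argmin(d2[i])] = 1.0
                continue
            for j in range(c):
                u_new[i, j] = 1.0 / np.sum((d2[i, j] / d2[i]) ** (1.0 / (m - 1.0)))
        u = u_new
        new_cost = float(np.sum((u ** m) * d2))
        if cost - new_cost < 1e-12 * max(cost, 1.0):
            cost = new_cost
            break
        cost = new_cost
    return cost, v


class TestFCM:
    def test_two_value_image_separates_exactly(self):
        rng = np.random.default_rng(0)
        pixels = np.where(rng.random((10, 10)) > 0.5, 0.0, -40.0)
        img = make_image(pixels)
        res = fcm_cluster(img, FCMParams(n_clusters=2, seed=0))
        np.testing.assert_allclose(np.sort(res.centroids), [-40.0, 0.0], atol=1e-6)
        np.testing.assert_array_equal(res.mask, pixels == 0.0)

    def test_pixel_at_centroid_gets_unit_membership(self):
        pixels = np.array([[-40.0, -40.0, -40.0, 0.0, 0.0, 0.0, -20.0, -19.0]])
        img = make_image(pixels)
        res = fcm_cluster(img, FCMParams(n_clusters=2, seed=1))
        # pixels exactly on a converged centroid are handled without division
        # by zero and memberships stay a valid partition
        assert np.all(np.isfinite(res.membership))
        np.testing.assert_allclose(res.membership.sum(axis=1), 1.0, atol=1e-12)

    def test_cost_non_increasing_and_memberships_valid(self):
        rng = np.random.default_rng(2)
        img = make_image(rng.uniform(-40, 0, size=(20, 30)))
        res = fcm_cluster(img, FCMParams(n_clusters=3, seed=2))
        assert np.all(np.diff(res.cost_history) <= 1e-9 * res.cost_history[:-1] + 1e-12)
        assert res.membership.min() >= 0.0 and res.membership.max() <= 1.0
        np.testing.assert_allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_restart_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-40.0, 0.0, size=50)
        img = make_image(x.reshape(5, 10))
        params = FCMParams(n_clusters=3, fuzziness=2.0, tol=1e-12,
                           max_iter=1000, seed=seed)
        res = fcm_cluster(img, params)
        best = min(
            brute_force_fcm(x, 3, 2.0, restart)[0] for restart in range(20)
        )
        assert res.cost_history[-1] == pytest.approx(best, abs=1e-6)

    def test_constant_image_is_degenerate(self):
        img = make_image(np.full((5, 5), -10.0))
        with pytest.raises(ValueError, match="degenerate"):
            fcm_cluster(img, FCMParams(n_clusters=2))

    def test_lesion_cluster_is_brightest(self):
        rng = np.random.default_rng(3)
        pixels = rng.choice([-40.0, -20.0, -1.0], size=(20, 20))
        img = make_image(pixels)
        res = fcm_cluster(img, FCMParams(n_clusters=3, seed=3))
        assert res.centroids[res.lesion_cluster] == res.centroids.max()

    def test_param_validation(self):
        for bad in (dict(n_clusters=1), dict(fuzziness=1.0), dict(tol=0.0),
                    dict(max_iter=0)):
            with pytest.raises(ValueError):
                FCMParams(**bad)


def as_lesion_mask(mask):
    mask = np.asarray(mask, bool)
    return LesionMask(mask=mask, membership=np.ones((mask.size, 1)),
                      centroids=np.array([0.0]), lesion_cluster=0)


class TestRefineMask:
    def test_isolated_pixel_removed_by_opening(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[1, 1] = True  # speck
        out = refine_mask(as_lesion_mask(mask), structuring_radius=1)
        assert not out.mask[1, 1]
        assert out.mask[7:13, 7:13].all()

    def test_interior_hole_filled_by_closing(self):
        mask = np.ones((20, 20), bool)
        mask[9, 9] = False
        out = refine_mask(as_lesion_mask(mask), structuring_radius=1)
        assert out.mask[9, 9]

    def test_opening_anti_extensive_closing_extensive(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mask = rng.random((30, 30)) > 0.6
            lm = as_lesion_mask(mask)
            opened = refine_mask(lm, structuring_radius=1, closing_radius=0,
                                 keep_largest=False).mask
            closed = refine_mask(lm, structuring_radius=0, closing_radius=1,
                                 keep_largest=False).mask
            assert np.all(opened <= mask)
            assert np.all(mask <= closed)

    def test_largest_component_kept(self):
        mask = np.zeros((30, 30), bool)
        mask[2:6, 2:6] = True       # 16 px
        mask[10:25, 10:25] = True   # 225 px
        out = refine_mask(as_lesion_mask(mask), structuring_radius=0)
        assert out.mask[12, 12] and not out.mask[3, 3]


class TestDepthTrace:
    def test_vertical_extent_arithmetic(self):
        mask = np.zeros((300, 12), bool)
        mask[100:200, :] = True  # rows 100..199 inclusive
        img = make_image(np.zeros((300, 12)) - 1.0, pitch_mm=0.01, laser_off=1)
        img.pixels[0, 0] = 0.0  # keep axes; pixels unused by depth_trace
        trace = depth_trace(as_lesion_mask(mask), img)
        assert trace.depth_mm[0] == pytest.approx(1.00)
        assert trace.final_depth_mm == pytest.approx(1.00)

    def test_empty_column_is_zero(self):
        mask = np.zeros((50, 6), bool)
        mask[10:20, 3] = True
        img = make_image(np.zeros((50, 6)) - 1.0, pitch_mm=0.02, laser_off=2)
        trace = depth_trace(as_lesion_mask(mask), img)
        assert trace.depth_mm[0] == 0.0
        assert trace.depth_mm[3] == pytest.approx(0.2)


class TestEndToEndTracking:
    def test_recovers_known_extent(self, single_procedure):
        truth = single_procedure["truth"]
        trace = single_procedure["trace"]
        assert abs(trace.final_depth_mm - truth.final_extent_mm) < 0.3

    def test_trace_zero_before_laser_on(self, single_procedure):
        image = single_procedure["image"]
        trace = single_procedure["trace"]
        assert np.all(trace.depth_mm[: image.laser_on_index] == 0.0)

    def test_trace_approximately_non_decreasing_during_ablation(self, single_procedure):
        image = single_procedure["image"]
        trace = single_procedure["trace"]
        growth = trace.depth_mm[image.laser_on_index: image.laser_off_index]
        active = growth[growth > 0]
        # violations only within about one closing-element height
        tol = 2 * 0.22 + 0.05
        assert np.all(np.diff(active) > -tol)

    def test_mmode_image_axes_and_range(self, single_procedure):
        image = single_procedure["image"]
        assert image.pixels.max() == 0.0
        assert image.pixels.min() >= -image.dynamic_range_db
        assert np.all(np.diff(image.depth_axis_mm) > 0)
        assert np.all(np.diff(image.time_axis_s) > 0)
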