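"""Back-projection and ground/non-ground classification."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from depthprop import (
    CameraModel,
    GROUND,
    INVALID,
    NON_GROUND,
    backproject,
    classify_ground_pixel,
    ground_mask,
)
from depthprop.geometry import Dialect, plane_signed_distance
from depthprop.scene import SceneConfig, Stalk, ground_point_at_depth, simulate_scene


# -- independent scalar oracle (kept deliberately naive) ------------------

def oracle_classify(x, z, h_c, alpha, t_f, dialect, x_g=None):
    if dialect == "plane_distance":
        return abs(z * math.sin(alpha) - x * math.cos(alpha) - h_c) <= t_f * h_c
    if x < 0:
        xg = -h_c / math.cos(alpha) if x_g is None else x_g
        denom = abs(xg) - abs(x)
        if denom <= 0:
            return False
        ratio = z / denom
        lo, hi = (1 - t_f) * math.tan(alpha), (1 + t_f) * math.tan(alpha)
    else:
        ratio = (h_c + x * math.cos(alpha)) / z
        lo, hi = (1 - t_f) * math.sin(alpha), (1 + t_f) * math.sin(alpha)
    return lo <= ratio <= hi


class TestBackproject:
    def test_principal_point_ray(self, simple_cam):
        depth = np.zeros((100, 100))
        depth[49, 49] = 2000.0  # pixel (cx, cy) = (49.5, 49.5) is not integral
        cam = CameraModel(fx=100, fy=100, cx=49, cy=49, width=100, height=100,
                          h_c=1.0, alpha=math.radians(30))
        pm = backproject(depth, cam)
        assert pm.valid[49, 49]
        np.testing.assert_allclose(
            (pm.x[49, 49], pm.y[49, 49], pm.z[49, 49]), (0.0, 0.0, 2.0)
        )

    def test_unit_focal_offset(self):
        cam = CameraModel(fx=10, fy=10, cx=5, cy=5, width=20, height=20,
                          h_c=1.0, alpha=math.radians(30))
        depth = np.zeros((20, 20))
        depth[5, 15] = 1000.0  # u = cx + fx, v = cy
        pm = backproject(depth, cam)
        np.testing.assert_allclose((pm.x[5, 15], pm.y[5, 15], pm.z[5, 15]), (1.0, 0.0, 1.0))

    def test_zero_depth_is_invalid(self, simple_cam):
        pm = backproject(np.zeros((100, 100)), simple_cam)
        assert not pm.valid.any()
        assert np.isnan(pm.z).all()

    def test_shape_mismatch_names_both_shapes(self, simple_cam):
        with pytest.raises(ValueError, match=r"\(50, 50\).*\(100, 100\)"):
            backproject(np.zeros((50, 50)), simple_cam)

    def test_negative_depth_rejected(self, simple_cam):
        d = np.zeros((100, 100))
        d[0, 0] = -1
        with pytest.raises(ValueError, match=">= 0"):
            backproject(d, simple_cam)


class TestClassifyGroundPixel:
    def test_band_centre_is_ground_for_any_tolerance(self):
        # h_c chosen as fl(2 sin a) so the ratio at z = 2 is *exactly* sin a
        a = math.radians(30)
        cam = CameraModel(fx=1, fy=1, cx=0, cy=0, width=2, height=2,
                          h_c=2 * math.sin(a), alpha=a)
        assert classify_ground_pixel((0.0, 0.3, 2.0), cam, t_f=0.0)

    def test_out_of_band_point_is_non_ground(self, simple_cam):
        # ratio = 1/3 outside [0.45, 0.55] = sin30 * (1 +- 0.1)
        assert not classify_ground_pixel((0.0, 0.0, 3.0), simple_cam, t_f=0.1)
        assert classify_ground_pixel((0.0, 0.0, 2.0), simple_cam, t_f=1e-9)

    def test_plane_distance_zero_residual(self, simple_cam):
        a = simple_cam.alpha
        z = 1.7
        x = (z * math.sin(a) - simple_cam.h_c) / math.cos(a)
        d = plane_signed_distance(x, z, simple_cam)
        assert abs(d) < 1e-12
        assert classify_ground_pixel((x, 0.0, z), simple_cam, t_f=1e-9,
                                     dialect="plane_distance")

    def test_negative_x_branch_hand_value(self, simple_cam):
        # x = -0.5, x_g = -1/cos30: L = 1.1547 - 0.5; ground iff z/L = tan30
        L = 1.0 / math.cos(simple_cam.alpha) - 0.5
        z = L * math.tan(simple_cam.alpha)
        assert classify_ground_pixel((-0.5, 0.0, z), simple_cam, t_f=1e-9)
        assert not classify_ground_pixel((-0.5, 0.0, z * 1.5), simple_cam, t_f=0.1)

    def test_beyond_ground_intercept_warns_non_ground(self, simple_cam):
        x_g = simple_cam.x_ground_intercept  # -1/cos30 ~ -1.1547
        with pytest.warns(UserWarning, match="intercept"):
            assert not classify_ground_pixel((x_g - 0.1, 0.0, 1.0), simple_cam, t_f=0.5)

    def test_invalid_inputs_rejected(self, simple_cam):
        with pytest.raises(ValueError, match="z > 0"):
            classify_ground_pixel((0.0, 0.0, 0.0), simple_cam, t_f=0.1)
        with pytest.raises(ValueError, match="t_f"):
            classify_ground_pixel((0.0, 0.0, 1.0), simple_cam, t_f=-0.1)


class TestGroundMask:
    def test_all_invalid_depth_gives_empty_partition(self, simple_cam):
        gm = ground_mask(backproject(np.zeros((100, 100)), simple_cam), simple_cam, 0.1)
        assert gm.n_ground == 0 and gm.n_non_ground == 0
        assert (gm.labels == INVALID).all()

    @pytest.mark.parametrize("dialect", ["piecewise", "plane_distance"])
    def test_partition_covers_every_pixel(self, simple_cam, rng, dialect):
        depth = rng.uniform(0, 4000, size=(100, 100))
        depth[rng.random((100, 100)) < 0.2] = 0.0
        pm = backproject(depth, simple_cam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = ground_mask(pm, simple_cam, 0.1, dialect)
        n_inv = int((gm.labels == INVALID).sum())
        assert gm.n_ground + gm.n_non_ground + n_inv == 100 * 100
        assert (gm.labels[~pm.valid] == INVALID).all()

    @pytest.mark.parametrize("dialect", ["piecewise", "plane_distance"])
    def test_agrees_with_scalar_oracle(self, simple_cam, rng, dialect):
        depth = rng.uniform(100, 4000, size=(40, 40))
        cam = CameraModel(fx=30, fy=30, cx=19.5, cy=19.5, width=40, height=40,
                          h_c=1.0, alpha=math.radians(30))
        pm = backproject(depth, cam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = ground_mask(pm, cam, 0.15, dialect)
        for r in range(40):
            for c in range(40):
                want = oracle_classify(pm.x[r, c], pm.z[r, c], cam.h_c, cam.alpha,
                                       0.15, dialect)
                assert (gm.labels[r, c] == GROUND) == want, (r, c)

    @pytest.mark.parametrize("dialect", ["piecewise", "plane_distance"])
    def test_monotone_in_tolerance(self, simple_cam, rng, dialect):
        depth = rng.uniform(100, 4000, size=(50, 50))
        cam = CameraModel(fx=40, fy=40, cx=24.5, cy=24.5, width=50, height=50,
                          h_c=1.0, alpha=math.radians(30))
        pm = backproject(depth, cam)
        prev = None
        for t_f in (0.0, 0.05, 0.1, 0.3, 1.0):
            g = ground_mask(pm, cam, t_f, dialect).is_ground
            if prev is not None:
                assert (prev <= g).all(), f"P_g not nested at t_f={t_f}"
            prev = g

    @given(z=st.floats(0.5, 5.0), frac=st.floats(-0.4, 0.9))
    def test_on_plane_points_with_positive_x_always_ground(self, z, frac):
        # Eq-style x >= 0 band is algebraically exact on the plane
        a = math.radians(35)
        h_c = 0.45
        cam = CameraModel(fx=1, fy=1, cx=0, cy=0, width=2, height=2, h_c=h_c, alpha=a)
        x = (z * math.sin(a) - h_c) / math.cos(a) + 0.0
        if x < 0:
            return
        assert classify_ground_pixel((x, 0.0, z), cam, t_f=1e-9)

    def test_noiseless_scene_mask_matches_rendered_labels(self, small_cam):
        stalk = Stalk(ground_point_at_depth(small_cam, 0.8), 0.2, 0.013)
        cfg = SceneConfig(camera=small_cam, stalks=[stalk],
                          depth_noise_sigma_mm=0.0, seed=3)
        scene = simulate_scene(cfg)
        pm = backproject(scene.depth_mm, small_cam)
        gm = ground_mask(pm, small_cam, t_f=1e-9, dialect="plane_distance")
        np.testing.assert_array_equal(gm.is_ground, scene.true_ground)

    def test_zero_tolerance_rejects_noisy_ground_and_recall_grows(self, small_cam):
        cfg = SceneConfig(camera=small_cam, stalks=[], depth_noise_sigma_mm=3.0, seed=5)
        scene = simulate_scene(cfg)
        pm = backproject(scene.depth_mm, small_cam)
        recalls = []
        for t_f in (0.0, 0.01, 0.05, 0.1):
            gm = ground_mask(pm, small_cam, t_f, "plane_distance")
            recalls.append(gm.is_ground[scene.true_ground].mean())
        assert recalls[0] < 0.01
        assert all(a <= b for a, b in zip(recalls, recalls[1:]))
        assert recalls[-1] > 0.95
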