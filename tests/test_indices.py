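import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockvision import (
    CameraGeometry,
    SegmentationParams,
    calibration_factor,
    cluster_index,
    compute_index_series,
    directed_hausdorff,
    symmetric_hausdorff,
    unrest_index,
)
from flockvision.errors import (
    EmptyForegroundError,
    InvalidFrameError,
    ParameterError,
)
from flockvision.segmentation import FrameShapeSet, ShapeDescriptor

from conftest import disk_mask, make_sequence


def euclid(a, b):
    dr, dc = float(a[0]) - float(b[0]), float(a[1]) - float(b[1])
    return math.sqrt(dr * dr + dc * dc)


def brute_force_directed(A, B):
    """Independent O(|A|·|B|) oracle for the directed Hausdorff distance."""
    return max(min(euclid(a, b) for b in B) for a in A)


def brute_force_symmetric(A, B):
    return max(brute_force_directed(A, B), brute_force_directed(B, A))


def tabulated_shape_set(a_bar=100.0, p_bar=40.0, d_bar=60.0, n=2, h=100, w=100):
    """FrameShapeSet fixture with prescribed summary statistics.

    n identical descriptors with the target mean area/perimeter, centroids
    equally spaced along a row so that for n = 2 the mean pairwise distance
    is exactly d_bar.
    """
    shapes = [
        ShapeDescriptor(
            area_px2=int(a_bar), perimeter_px=p_bar, centroid=(10.0, 10.0 + i * d_bar)
        )
        for i in range(n)
    ]
    return FrameShapeSet(
        frame_index=0,
        shapes=shapes,
        frame_height_px=h,
        frame_width_px=w,
        mask=np.zeros((h, w), dtype=bool),
    )


class TestCalibrationFactor:
    def test_closed_form_unit_case(self, unit_geometry):
        # tan(45°) = 1: field of view equals 2H, 20 cm across 20 px
        assert calibration_factor(unit_geometry) == pytest.approx(1.0)

    def test_ceiling_camera_value(self):
        geom = CameraGeometry(300, 60, 976)
        expected = 2 * 300 * math.tan(math.radians(30)) / 976
        assert calibration_factor(geom) == pytest.approx(expected)
        assert calibration_factor(geom) == pytest.approx(0.3549, abs=2e-4)

    def test_linear_in_height(self):
        k1 = calibration_factor(CameraGeometry(150, 75, 500))
        k2 = calibration_factor(CameraGeometry(300, 75, 500))
        assert k2 == pytest.approx(2 * k1)

    @pytest.mark.parametrize("angle", [0, -10, 180, 200])
    def test_invalid_angles_rejected(self, angle):
        with pytest.raises(ParameterError):
            CameraGeometry(100, angle, 500)


class TestHausdorff:
    def test_identical_sets_give_zero(self):
        pts = np.array([[0, 0], [3, 1], [7, 2]])
        assert symmetric_hausdorff(pts, pts) == 0.0

    def test_asymmetry_of_directed_distance(self):
        A = np.array([[0, 0], [0, 3]])
        B = np.array([[0, 1]])
        assert directed_hausdorff(A, B) == pytest.approx(2.0)
        assert directed_hausdorff(B, A) == pytest.approx(1.0)
        assert symmetric_hausdorff(A, B) == pytest.approx(2.0)

    def test_singletons_reduce_to_euclidean_distance(self):
        A, B = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert directed_hausdorff(A, B) == 5.0
        assert directed_hausdorff(B, A) == 5.0

    def test_empty_set_rejected(self):
        with pytest.raises(EmptyForegroundError):
            directed_hausdorff(np.empty((0, 2)), np.array([[0, 0]]))

    def test_matches_brute_force_oracle_on_many_seeded_instances(self):
        """Exact agreement with the double-loop oracle on 200 random pairs."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            nA, nB = rng.integers(1, 51, size=2)
            A = rng.uniform(0, 100, size=(nA, 2))
            B = rng.uniform(0, 100, size=(nB, 2))
            assert symmetric_hausdorff(A, B) == brute_force_symmetric(A, B)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 50, size=(rng.integers(1, 20), 2))
        B = rng.uniform(0, 50, size=(rng.integers(1, 20), 2))
        assert symmetric_hausdorff(A, B) == symmetric_hausdorff(B, A)


class TestUnrestIndex:
    def test_static_scene_is_zero(self):
        mask = disk_mask((40, 40), (20, 20), 6)
        assert unrest_index(mask, mask, k=0.7) == 0.0

    def test_translated_disk_measures_translation_length(self):
        # disk moved by (3, 4) px with k = 2 → 2 · 5 px = 10 cm
        prev = disk_mask((60, 60), (25, 25), 8)
        curr = disk_mask((60, 60), (28, 29), 8)
        assert unrest_index(curr, prev, k=2.0) == pytest.approx(10.0, abs=0.75 * 2.0)

    def test_zero_calibration_kills_motion(self):
        prev = disk_mask((40, 40), (15, 15), 5)
        curr = disk_mask((40, 40), (25, 25), 5)
        assert unrest_index(curr, prev, k=0.0) == 0.0

    def test_empty_foreground_is_flagged_not_zero(self):
        mask = disk_mask((20, 20), (10, 10), 4)
        with pytest.raises(EmptyForegroundError):
            unrest_index(np.zeros((20, 20), bool), mask, k=1.0)

    def test_mask_fast_path_equals_point_oracle(self):
        """EDT-based mask Hausdorff equals the brute-force double loop exactly."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = rng.random((18, 18)) < 0.1
            b = rng.random((18, 18)) < 0.1
            if not (a.any() and b.any()):
                continue
            expected = brute_force_symmetric(
                np.argwhere(a).tolist(), np.argwhere(b).tolist()
            )
            assert unrest_index(a, b, k=1.0) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_translation_of_convex_blob(self, seed):
        """Unrest of a translated disk is k·‖t‖ within discretization error."""
        rng = np.random.default_rng(seed)
        dr, dc = rng.integers(-6, 7, size=2)
        prev = disk_mask((50, 50), (25, 25), 7)
        curr = disk_mask((50, 50), (25 + dr, 25 + dc), 7)
        k = 0.5
        expected = k * math.hypot(dr, dc)
        assert unrest_index(curr, prev, k=k) == pytest.approx(expected, abs=0.75 * k)


class TestClusterIndex:
    def test_hand_computed_default_variant(self):
        # 2·100·√(100²+100²) / (40·60·1) ≈ 11.785
        ss = tabulated_shape_set()
        expected = 2 * 100 * math.hypot(100, 100) / (40 * 60 * 1)
        assert cluster_index(ss) == pytest.approx(expected)
        assert cluster_index(ss) == pytest.approx(11.785, abs=1e-3)

    def test_doubling_distance_halves_index(self):
        base = cluster_index(tabulated_shape_set(d_bar=60))
        far = cluster_index(tabulated_shape_set(d_bar=120))
        assert far == pytest.approx(base / 2)

    def test_na_inverse_variant_halves_two_blob_value(self):
        ss = tabulated_shape_set(n=2)
        assert cluster_index(ss, variant="nA_inverse") == pytest.approx(
            cluster_index(ss, variant="nA_minus_1") / 2
        )

    def test_non_diagonal_variant_uses_squared_sum(self):
        ss = tabulated_shape_set()
        ratio = cluster_index(ss, diagonal=False) / cluster_index(ss, diagonal=True)
        assert ratio == pytest.approx(math.hypot(100, 100))

    def test_single_blob_frame_is_invalid(self):
        with pytest.raises(InvalidFrameError):
            cluster_index(tabulated_shape_set(n=1))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.floats(1.1, 4.0),
        st.integers(0, 2**31 - 1),
    )
    def test_pixel_rescaling_scales_index_linearly(self, s, seed):
        """Ā→s²Ā, P̄→sP̄, D̄→sD̄, h→sh, w→sw multiplies the index by s."""
        rng = np.random.default_rng(seed)
        a, p, d = rng.uniform(50, 200), rng.uniform(20, 80), rng.uniform(30, 90)
        base = cluster_index(tabulated_shape_set(a, p, d))
        scaled = cluster_index(
            tabulated_shape_set(
                a * s * s, p * s, d * s, h=round(100 * s), w=round(100 * s)
            )
        )
        # integer frame dims introduce sub-percent rounding
        assert scaled == pytest.approx(s * base, rel=2e-2)

    def test_moving_blobs_apart_strictly_decreases_crowding(self):
        values = [
            cluster_index(tabulated_shape_set(d_bar=d)) for d in (30, 45, 60, 90)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestComputeIndexSeries:
    @pytest.fixture
    def static_two_blob_sequence(self):
        img = np.full((60, 80), 200, dtype=np.uint8)
        img[10:20, 10:20] = 30
        img[35:45, 50:60] = 30
        return make_sequence([img, img])

    @pytest.fixture
    def controlled_params(self):
        return SegmentationParams(
            lowpass_sigma=0.0,
            background_method="global_threshold",
            threshold_method="fixed",
            fixed_threshold=100.0,
            min_blob_area_px=0,
        )

    def test_static_pair_zero_unrest_equal_cluster(
        self, static_two_blob_sequence, controlled_params, unit_geometry
    ):
        series = compute_index_series(
            static_two_blob_sequence, controlled_params, unit_geometry
        )
        assert len(series.cluster_values) == 2
        assert len(series.unrest_values) == 1
        (_, u) = series.unrest_values[0]
        assert u == 0.0
        (_, c0, v0), (_, c1, v1) = series.cluster_values
        assert v0 and v1
        assert c0 == c1 > 0

    def test_pair_count_is_frames_minus_one(self, controlled_params, unit_geometry):
        rng = np.random.default_rng(0)
        imgs = []
        for t in range(6):
            img = np.full((40, 60), 200, dtype=np.uint8)
            r = 5 + 2 * t
            img[r : r + 6, 10:16] = 30
            img[20:26, 40:46] = 30
            imgs.append(img)
        series = compute_index_series(
            make_sequence(imgs), controlled_params, unit_geometry
        )
        assert len(series.cluster_values) == 6
        assert len(series.unrest_values) == 5

    def test_single_blob_frames_flagged_not_dropped(
        self, controlled_params, unit_geometry
    ):
        one = np.full((40, 40), 200, dtype=np.uint8)
        one[10:20, 10:20] = 30
        series = compute_index_series(
            make_sequence([one, one]), controlled_params, unit_geometry
        )
        assert [flag for _, _, flag in series.cluster_values] == [False, False]
        assert series.unrest_values[0][1] == 0.0

    def test_deterministic_and_fingerprinted(
        self, static_two_blob_sequence, controlled_params, unit_geometry
    ):
        s1 = compute_index_series(
            static_two_blob_sequence, controlled_params, unit_geometry
        )
        s2 = compute_index_series(
            static_two_blob_sequence, controlled_params, unit_geometry
        )
        assert s1.params_fingerprint == s2.params_fingerprint
        assert s1.to_dataframe().equals(s2.to_dataframe())

    def test_series_csv_roundtrip(
        self, static_two_blob_sequence, controlled_params, unit_geometry, tmp_path
    ):
        import pandas as pd

        series = compute_index_series(
            static_two_blob_sequence, controlled_params, unit_geometry
        )
        path = tmp_path / "series.csv"
        series.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "frame_index", "timestamp_s", "cluster_index", "valid", "unrest_cm",
        ]
        assert len(df) == 2


def test_analysis_config_yaml(tmp_path):
    """Geometry and segmentation blocks read from one YAML config."""
    from flockvision.indices import load_config

    path = tmp_path / "analysis.yaml"
    path.write_text(
        "geometry:\n"
        "  mount_height_cm: 300\n"
        "  lens_angle_deg: 60\n"
        "  sensor_length_px: 976\n"
        "segmentation:\n"
        "  lowpass_sigma: 2.0\n"
        "  min_blob_area_px: 30\n"
    )
    cfg = load_config(path)
    assert cfg["geometry"].k_cm_per_px == pytest.approx(0.3549, abs=2e-4)
    assert cfg["segmentation"].lowpass_sigma == 2.0
    assert cfg["segmentation"].min_blob_area_px == 30
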