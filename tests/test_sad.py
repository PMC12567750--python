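"""SAD profile computation, box statistics and path-length histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirscalib import (
    compute_sad_profile,
    mean_sad_across_heads,
    pathlength_histogram,
    sad_box_stats,
)
from nirscalib.sad import SADProfile
from nirscalib.transport import DetectedPhotons, FluenceVolume


def volume(values):
    return FluenceVolume(values=np.asarray(values, dtype=float), voxel_size=1.0)


def brute_force_disk_count(n, center, radius):
    """Exhaustive voxel-centre-in-disk enumeration over an n x n plane."""
    count = 0
    for i in range(n):
        for j in range(n):
            if ((i + 0.5) - center[0]) ** 2 + ((j + 0.5) - center[1]) ** 2 <= radius**2:
                count += 1
    return count


class TestComputeSadProfile:
    def test_delta_fluence_all_in_one_layer(self):
        vals = np.zeros((64, 64, 64))
        vals[32, 32, 5] = 7.0  # single voxel on the midpoint column
        prof = compute_sad_profile(volume(vals), midpoint_xy=(32.0, 32.0))
        assert prof.sad[5] == pytest.approx(100.0)
        assert prof.sad.sum() == pytest.approx(100.0)
        assert (np.delete(prof.sad, 5) == 0).all()

    def test_uniform_fluence_matches_brute_force_count(self):
        vals = np.ones((64, 64, 64))
        prof = compute_sad_profile(volume(vals), midpoint_xy=(32.0, 32.0), roi_radius=10.0)
        count = brute_force_disk_count(64, (32.0, 32.0), 10.0)
        expected = count / 64**3 * 100.0
        assert np.allclose(prof.sad, expected)

    def test_two_equal_point_masses_split_evenly(self):
        vals = np.zeros((64, 64, 64))
        vals[32, 32, 3] = 2.5  # inside the ROI
        vals[2, 2, 3] = 2.5  # far outside the ROI
        prof = compute_sad_profile(volume(vals), midpoint_xy=(32.0, 32.0))
        assert prof.sad[3] == pytest.approx(50.0)

    def test_all_zero_fluence_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_sad_profile(volume(np.zeros((8, 8, 8))))

    def test_midpoint_from_metadata(self):
        vals = np.zeros((64, 64, 64))
        vals[20, 32, 4] = 1.0
        vol = FluenceVolume(
            values=vals,
            voxel_size=1.0,
            meta={"source_xy_mm": [15.0, 32.0], "detector_xy_mm": [25.0, 32.0]},
        )
        prof = compute_sad_profile(vol)  # midpoint (20, 32): mass inside ROI
        assert prof.sad[4] == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(1e-6, 1e6), seed=st.integers(0, 2**16))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((16, 16, 16)) + 1e-9
        p1 = compute_sad_profile(volume(vals), midpoint_xy=(8.0, 8.0), roi_radius=5.0)
        p2 = compute_sad_profile(volume(vals * scale), midpoint_xy=(8.0, 8.0), roi_radius=5.0)
        assert np.allclose(p1.sad, p2.sad, rtol=1e-9)
        assert p1.sad.sum() <= 100.0 + 1e-9


class TestSensitivityVolume:
    def test_mirror_symmetric_by_construction(self):
        rng = np.random.default_rng(1)
        from nirscalib.sad import sensitivity_volume

        vol = volume(rng.random((16, 16, 16)))
        sens = sensitivity_volume(vol)
        assert np.allclose(sens.values, np.flip(sens.values, axis=0))
        assert (sens.values >= 0).all()
        assert sens.meta.get("field") == "sensitivity"

    def test_product_of_source_and_mirrored_source(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 1, 2] = 2.0
        vals[3, 1, 2] = 5.0  # mirrored partner along x
        from nirscalib.sad import sensitivity_volume

        sens = sensitivity_volume(volume(vals))
        assert sens.values[0, 1, 2] == pytest.approx(10.0)
        assert sens.values[3, 1, 2] == pytest.approx(10.0)
        assert sens.values.sum() == pytest.approx(20.0)

    def test_roi_normalization_sums_to_hundred(self):
        rng = np.random.default_rng(2)
        vals = rng.random((64, 64, 64))
        prof = compute_sad_profile(
            volume(vals), midpoint_xy=(32.0, 32.0), normalization="roi"
        )
        assert prof.sad.sum() == pytest.approx(100.0)

    def test_unknown_normalization_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            compute_sad_profile(volume(np.ones((8, 8, 8))), normalization="bogus")


class TestMeanAcrossHeads:
    def test_single_profile_is_identity(self):
        p = SADProfile(head_id=1, sds=19.0, sad=np.arange(64.0))
        m = mean_sad_across_heads([p])
        assert np.array_equal(m.sad, p.sad)

    def test_two_profiles_average(self):
        a = SADProfile(head_id=1, sds=19.0, sad=np.full(64, 2.0))
        b = SADProfile(head_id=2, sds=19.0, sad=np.full(64, 4.0))
        m = mean_sad_across_heads([a, b])
        assert np.allclose(m.sad, 3.0)

    def test_mixed_sds_rejected(self):
        a = SADProfile(head_id=1, sds=19.0, sad=np.zeros(64))
        b = SADProfile(head_id=2, sds=21.0, sad=np.zeros(64))
        with pytest.raises(ValueError, match="mix"):
            mean_sad_across_heads([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_sad_across_heads([])


class TestBoxStats:
    def test_linear_interpolation_quantiles(self):
        stats = sad_box_stats([1, 2, 3, 4, 5, 6, 7, 8])
        assert stats.median == pytest.approx(4.5)
        assert stats.q1 == pytest.approx(2.75)
        assert stats.q3 == pytest.approx(6.25)
        assert stats.outliers == ()

    def test_constant_values_have_no_outliers(self):
        stats = sad_box_stats([5.0] * 6)
        assert stats.iqr == 0
        assert stats.outliers == ()
        assert stats.whisker_low == stats.whisker_high == 5.0

    def test_extreme_value_flagged_as_outlier(self):
        stats = sad_box_stats([1, 1, 1, 1, 1, 1, 1, 100])
        assert stats.outliers == (100.0,)
        assert stats.whisker_high == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            sad_box_stats([1, 2, 3])

    @settings(derandomize=True, max_examples=30)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=30),
    )
    def test_box_invariants(self, values):
        stats = sad_box_stats(values)
        assert stats.q1 <= stats.median <= stats.q3
        assert stats.whisker_low >= stats.q1 - 1.5 * stats.iqr - 1e-9
        assert stats.whisker_high <= stats.q3 + 1.5 * stats.iqr + 1e-9
        for out in stats.outliers:
            assert out < stats.q1 - 1.5 * stats.iqr or out > stats.q3 + 1.5 * stats.iqr


class TestPathLengthHistogram:
    def test_single_record(self):
        det = DetectedPhotons([0.5], [30.0], [0.0], [0.0])
        hist = pathlength_histogram(det, n_bins=5)
        assert hist.mean_weight.max() == pytest.approx(0.5)
        assert hist.counts.sum() == 1

    def test_two_records_two_bins(self):
        det = DetectedPhotons([0.2, 0.4], [10.0, 50.0], [0, 0], [0, 0])
        hist = pathlength_histogram(det, n_bins=2)
        assert hist.mean_weight == pytest.approx([0.2, 0.4])
        assert hist.counts.tolist() == [1, 1]

    def test_empty_rejected(self):
        det = DetectedPhotons([], [], [], [])
        with pytest.raises(ValueError):
            pathlength_histogram(det)

    def test_detected_mean_path_grows_with_separation(self, head1_phantom):
        # longer separations require longer photon paths; a wide detector
        # aperture keeps desk-scale detection statistics usable
        from nirscalib import SimulationConfig, run_simulation

        means = []
        for sds in (19.0, 31.0):
            cfg = SimulationConfig(n_photons=100_000, seed=8, detector_radius=6.0)
            _, det, _ = run_simulation(head1_phantom, sds=sds, config=cfg)
            assert len(det) > 5
            hist = pathlength_histogram(det, n_bins=15)
            assert (hist.mean_weight >= 0).all()
            means.append(hist.mean_path_length())
        assert means[1] > means[0]
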