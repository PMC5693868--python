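import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from furrowsim.pulse_analysis import (
    IntensityTrace,
    PulseAnalysisError,
    PulseFit,
    analyze_trace,
    detect_pulse_segments,
    extract_traces,
    filter_pulses,
    fit_pulse,
    partition_pools,
    pulse_model,
    pulse_statistics,
)
from furrowsim.synthetic_data import SceneGenSpec, gen_scene


def make_trace(y, dt=12.0, cell_id=0):
    y = np.asarray(y, dtype=float)
    return IntensityTrace.from_raw(cell_id, np.arange(len(y)) * dt, y)


class TestPartitionPools:
    def test_exact_decomposition_any_mask(self, rng):
        mask = rng.integers(0, 4, (40, 40))
        image = rng.uniform(0, 100, (40, 40))
        pools = partition_pools(mask, image)
        np.testing.assert_array_equal(
            pools["medial_sum"] + pools["junctional_sum"], pools["total_sum"]
        )
        np.testing.assert_array_equal(
            pools["medial_px"] + pools["junctional_px"], pools["total_px"]
        )

    def test_three_pixel_band_on_rectangular_cell(self):
        mask = np.zeros((30, 40), dtype=int)
        mask[5:25, 5:35] = 1  # 20 x 30 cell
        pools = partition_pools(mask, np.ones_like(mask, dtype=float))
        # three single-pixel erosions strip exactly 3 px from each side
        assert pools.loc[0, "medial_px"] == (20 - 6) * (30 - 6)
        # band width along a straight boundary segment is 3 px
        cell = mask == 1
        from scipy import ndimage

        medial = ndimage.binary_erosion(
            cell, ndimage.generate_binary_structure(2, 1), iterations=3
        )
        band = cell & ~medial
        mid_row = band[15, :]
        runs = np.flatnonzero(mid_row)
        assert list(runs[:3]) == [5, 6, 7] and list(runs[-3:]) == [32, 33, 34]

    def test_five_by_five_cell_fully_eroded(self):
        mask = np.zeros((9, 9), dtype=int)
        mask[2:7, 2:7] = 1
        with pytest.warns(UserWarning, match="medial region empty"):
            pools = partition_pools(mask, np.ones((9, 9)))
        assert pools.loc[0, "medial_px"] == 0
        assert pools.loc[0, "junctional_sum"] == pools.loc[0, "total_sum"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(PulseAnalysisError, match="shape"):
            partition_pools(np.zeros((4, 4), dtype=int), np.zeros((5, 5)))

    def test_scene_pool_ratio_recovered(self):
        scene = gen_scene(SceneGenSpec(seed=5, cell_px=64, rows=2, cols=2,
                                       junctional=300.0, medial=100.0,
                                       noise_sd=3.0))
        pools = partition_pools(scene.mask, scene.myosin)
        ratio = pools["junctional_mean"] / pools["medial_mean"]
        np.testing.assert_allclose(ratio, 3.0, rtol=0.05)

    def test_scene_zero_medial(self):
        scene = gen_scene(SceneGenSpec(seed=5, cell_px=32, medial=0.0,
                                       noise_sd=0.0))
        pools = partition_pools(scene.mask, scene.myosin)
        np.testing.assert_allclose(pools["medial_mean"], 0.0, atol=1e-12)


class TestExtractTraces:
    def test_constant_stack_normalizes_to_one(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[2:12, 2:12] = 1
        stack = np.full((8, 20, 20), 37.0)
        traces = extract_traces(mask, stack, pool="total")
        assert len(traces) == 1
        np.testing.assert_allclose(traces[0].normalized, 1.0)
        np.testing.assert_allclose(traces[0].t_s, np.arange(8) * 12.0)

    def test_background_subtraction_flattens_flat_field(self):
        from furrowsim.pulse_analysis import subtract_background

        # a flat field is pure background: no structure survives subtraction
        flat = np.full((20, 20), 50.0)
        out = subtract_background(flat, radius=100.0)
        assert np.ptp(out) < 1e-9
        assert np.abs(out).max() < 1e-6

    def test_scene_means_match_generator_truth(self):
        scene = gen_scene(SceneGenSpec(seed=2, cell_px=32, noise_sd=2.0))
        stack = np.repeat(scene.myosin[None], 4, axis=0)
        traces = extract_traces(scene.mask, stack, pool="medial")
        got = {tr.cell_id: tr.raw[0] for tr in traces}
        for _, row in scene.truth.iterrows():
            n_px = (scene.mask == row["cell_id"]).sum()
            tol = 3 * 2.0 / np.sqrt(n_px / 4)  # generous noise bound
            assert abs(got[row["cell_id"]] - row["medial_mean"]) < tol

    def test_z_stack_is_max_projected(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:8, 2:8] = 1
        stack = np.zeros((2, 3, 10, 10))
        stack[:, 1] = 9.0  # brightest section
        traces = extract_traces(mask, stack, pool="total")
        np.testing.assert_allclose(traces[0].raw, 9.0)


class TestSegmentation:
    def test_strictly_monotone_trace_has_no_segments(self):
        tr = make_trace(100 + np.arange(30.0))
        assert detect_pulse_segments(tr) == []

    def test_single_gaussian_yields_one_segment_spanning_bump(self):
        x = np.arange(60.0)
        y = 100.0 + 80.0 * np.exp(-(((x - 30) / 4.0) ** 2))
        segs = detect_pulse_segments(make_trace(y))
        assert len(segs) == 1
        start, stop, peak = segs[0]
        assert start <= 26 and stop >= 34
        assert abs(peak - 30) <= 1

    def test_two_separated_gaussians_split_at_true_minimum(self):
        x = np.arange(80.0)
        c1 = 4.0
        y = (100.0
             + 80.0 * np.exp(-(((x - 20) / c1) ** 2))
             + 60.0 * np.exp(-(((x - 55) / c1) ** 2)))
        segs = detect_pulse_segments(make_trace(y))
        assert len(segs) == 2
        boundary = segs[0][1]
        true_min = 20 + np.argmin(y[20:56])
        assert abs(boundary - true_min) <= 1

    def test_too_short_trace_rejected(self):
        with pytest.raises(PulseAnalysisError, match="5 samples"):
            detect_pulse_segments(make_trace([1, 2, 3, 4]))


class TestFit:
    def test_noiseless_parameter_recovery(self):
        truth = dict(a0=0.01, b0=1.0, a1=0.8, b1=10.0, c1=3.0)
        x = np.arange(25.0)
        y = pulse_model(x, **truth)
        fit = fit_pulse(x, y)
        for name, val in truth.items():
            assert getattr(fit, name) == pytest.approx(val, rel=1e-6)
        assert fit.residual_norm < 1e-8

    def test_flat_segment_yields_null_amplitude_and_discard(self):
        x = np.arange(12.0)
        y = np.full_like(x, 1.0)
        fit = fit_pulse(x, y)
        assert fit.a1 < 1e-6
        tr = make_trace(np.full(12, 100.0))
        retained = filter_pulses([fit], tr)
        assert retained == [] and fit.status == "discarded"

    def test_model_identity_at_centroid(self):
        fit = PulseFit(0, (0, 10), a0=0.02, b0=1.1, a1=0.5, b1=4.0, c1=2.0,
                       residual_norm=0.0)
        assert fit.value(fit.b1) == pytest.approx(
            fit.a0 * fit.b1 + fit.b0 + fit.a1, rel=1e-15
        )

    def test_deterministic(self):
        x = np.arange(20.0)
        y = pulse_model(x, 0.0, 1.0, 0.6, 8.0, 2.5) + 0.01 * np.sin(x)
        f1, f2 = fit_pulse(x, y), fit_pulse(x, y)
        assert (f1.a0, f1.b0, f1.a1, f1.b1, f1.c1) == (
            f2.a0, f2.b0, f2.a1, f2.b1, f2.c1
        )


class TestFilter:
    def fits(self, amplitudes):
        return [
            PulseFit(0, (0, 10), 0.0, 1.0, a, 5.0, 2.0, residual_norm=0.0)
            for a in amplitudes
        ]

    def test_threshold_boundary(self):
        tr = make_trace(np.full(10, 200.0))
        fits = self.fits([0.24, 0.25, 0.0, 0.26])
        retained = filter_pulses(fits, tr)
        assert [f.a1 for f in retained] == [0.25, 0.26]
        assert fits[0].status == "discarded"
        assert fits[2].status == "discarded"

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_filter_commutes_with_raw_rescaling(self, scale):
        """Scaling raw intensities leaves retained/discarded unchanged."""
        x = np.arange(52.0)
        y = (100.0
             + 0.2 * x
             + 15.0 * np.exp(-(((x - 15) / 3.0) ** 2))    # sub-threshold
             + 80.0 * np.exp(-(((x - 38) / 3.0) ** 2)))   # supra-threshold
        base = [f.status for f in analyze_trace(make_trace(y))]
        scaled = [f.status for f in analyze_trace(make_trace(y * scale))]
        assert base == scaled
        assert base.count("retained") == 1


class TestStatistics:
    def test_single_cell_two_pulses(self):
        fits = [
            PulseFit(0, (0, 10), 0.0, 1.0, 0.5, 3.0, 2.0, residual_norm=0.0),
            PulseFit(0, (10, 20), 0.0, 1.0, 0.6, 14.0, 2.0, residual_norm=0.0),
        ]
        stats = pulse_statistics({0: fits})
        assert stats["pulses_per_cell_mean"] == 2.0
        assert stats["pulses_per_cell_sd"] == 0.0

    def test_cumulative_distribution_properties(self, rng):
        fits = {
            c: [
                PulseFit(c, (0, 9), 0.0, 1.0, 0.5, float(b1), 2.0,
                         residual_norm=0.0)
                for b1 in rng.uniform(0, 50, rng.integers(0, 5))
            ]
            for c in range(20)
        }
        stats = pulse_statistics(fits)
        cum = stats["cumulative_counts"]
        assert np.all(np.diff(stats["cumulative_times"]) >= 0)
        assert np.all(np.diff(cum) >= 0)
        assert (cum[-1] if len(cum) else 0) == stats["total_retained"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(PulseAnalysisError, match="one cell"):
            pulse_statistics({})
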