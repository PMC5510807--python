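import numpy as np
import pytest

import ciliaflow as cf
from ciliaflow import NoDominantFrequency, NoMeasurablePeriod, \
    WavelengthNotMeasurable
from conftest import make_small_spec


def _flat_line(y=4.0, x1=20.0):
    x = np.linspace(1.0, x1, 5)
    return cf.EdgePolyline(np.column_stack([x, np.full(5, y)]))


def _stack_from_signal(signal, shape=(24, 80), frame_rate=358.0,
                       pixel_size=0.32):
    data = 128.0 + signal[:, None, None] * np.ones(shape)[None]
    return cf.FrameStack(data=data, frame_rate=frame_rate,
                         pixel_size=pixel_size)


class TestCbfFFT:
    def test_recovers_generator_cbf_within_one_bin(self, small_movie,
                                                   small_spec):
        stack, truth = small_movie
        line = small_spec.edge_polyline.offset(3.0)
        cbf, (freqs, power) = cf.cbf_fft(stack, line)
        bin_width = stack.frame_rate / stack.n_frames
        assert cbf == pytest.approx(truth.cbf, abs=bin_width)
        assert len(freqs) == len(power)

    def test_two_tone_signal_picks_dominant_component(self):
        """7 Hz at amplitude 10 vs 20 Hz at amplitude 2: the analytic
        spectrum peaks at 7 Hz."""
        t = np.arange(716) / 358.0
        sig = 10 * np.sin(2 * np.pi * 7 * t) + 2 * np.sin(2 * np.pi * 20 * t)
        stack = _stack_from_signal(sig)
        cbf, _ = cf.cbf_fft(stack, _flat_line())
        assert cbf == pytest.approx(7.0, abs=0.5)

    def test_constant_movie_has_no_dominant_frequency(self):
        stack = _stack_from_signal(np.zeros(256))
        with pytest.raises(NoDominantFrequency):
            cf.cbf_fft(stack, _flat_line())

    def test_band_validation(self):
        stack = _stack_from_signal(np.sin(np.arange(256)))
        with pytest.raises(ValueError):
            cf.cbf_fft(stack, _flat_line(), f_min=10.0, f_max=5.0)

    def test_polyline_outside_image_names_point(self, small_movie):
        stack, _ = small_movie
        bad = cf.EdgePolyline([[0, 4], [10, 4], [20, 4], [30, 4],
                               [999.0, 4]])
        with pytest.raises(ValueError, match="999"):
            cf.cbf_fft(stack, bad)


class TestKymograph:
    def test_static_movie_rows_identical(self):
        stack = _stack_from_signal(np.zeros(64))
        stack.data += np.random.default_rng(0).normal(
            0, 5, stack.data.shape[1:])[None]     # static texture
        kymo = cf.build_kymograph(stack, _flat_line())
        assert np.allclose(kymo.data, kymo.data[0][None])

    def test_autocorrelation_peaks_at_beat_period(self, small_wall):
        spec = make_small_spec(small_wall, cbf=10.0)
        stack, _ = cf.generate_movie(spec)
        kymo = cf.build_kymograph(stack, small_wall.offset(3.0))
        x = kymo.data - kymo.data.mean(axis=0)
        ac = sum(np.correlate(x[:, j], x[:, j], "full")[len(x) - 1:]
                 for j in range(x.shape[1]))
        lag = np.argmax(ac[18:54]) + 18     # first peak region
        assert lag == pytest.approx(358.0 / 10.0, abs=1.0)

    def test_cbf_from_kymograph_matches_fft_methods(self, small_wall):
        """Cross-method agreement within one FFT bin for a range of beat
        frequencies on noiseless movies."""
        for cbf_true in (4.0, 8.0, 14.0):
            spec = make_small_spec(small_wall, cbf=cbf_true)
            stack, _ = cf.generate_movie(spec)
            line = small_wall.offset(3.0)
            bin_width = stack.frame_rate / stack.n_frames
            f_fft, _ = cf.cbf_fft(stack, line)
            f_kymo = cf.cbf_kymograph(cf.build_kymograph(stack, line))
            assert f_fft == pytest.approx(cbf_true, abs=bin_width)
            assert f_kymo == pytest.approx(f_fft, abs=bin_width)

    def test_pure_sine_period(self):
        """5 Hz sine sampled at 358 fps: autocorrelation comb gives the
        period to sub-lag precision."""
        t = np.arange(1024) / 358.0
        stack = _stack_from_signal(20 * np.sin(2 * np.pi * 5 * t))
        kymo = cf.build_kymograph(stack, _flat_line())
        assert cf.cbf_kymograph(kymo) == pytest.approx(5.0, abs=0.05)

    def test_constant_movie_raises(self):
        stack = _stack_from_signal(np.zeros(64))
        kymo = cf.build_kymograph(stack, _flat_line())
        with pytest.raises(NoMeasurablePeriod):
            cf.cbf_kymograph(kymo)


class TestCba:
    @pytest.mark.parametrize("p0,p1,p2,cba,length", [
        ((0, 0), (0, 6), (6, 0), 6 * np.sqrt(2), 6.0),
        ((0, 0), (3, 4), (-3, 4), 6.0, 5.0),
    ])
    def test_hand_geometry(self, p0, p1, p2, cba, length):
        got_cba, got_len = cf.measure_cba(p0, p1, p2)
        assert got_cba == pytest.approx(cba)
        assert got_len == pytest.approx(length)

    def test_degenerate_beat_warns(self):
        with pytest.warns(UserWarning):
            cba, _ = cf.measure_cba((0, 0), (2, 2), (2, 2))
        assert cba == 0.0


class TestWavelength:
    def test_recovers_generator_wavelength(self, small_movie, small_spec):
        stack, truth = small_movie
        fit = cf.metachronal_wavelength(stack,
                                        small_spec.edge_polyline.offset(3.0))
        assert fit.wavelength == pytest.approx(truth.wavelength, rel=0.10)
        assert fit.r2 > 0.99

    def test_invariant_under_segment_order_reversal(self, small_movie,
                                                    small_spec):
        stack, _ = small_movie
        line = small_spec.edge_polyline.offset(3.0)
        lam_fwd = cf.metachronal_wavelength(stack, line).wavelength
        lam_rev = cf.metachronal_wavelength(stack,
                                            line.reversed()).wavelength
        assert lam_rev == pytest.approx(lam_fwd, rel=0.02)

    def test_exact_phase_ramp(self):
        """A constructed phase field with one full turn per 16.7 μm gives
        exactly that wavelength."""
        t = np.arange(256)[:, None, None] / 358.0
        x_um = (np.arange(100)[None, None, :] + 0.5) * 0.32
        data = 128.0 + 40.0 * np.sin(
            2 * np.pi * 9.0 * t - 2 * np.pi * x_um / 16.7
        ) * np.ones((1, 16, 1))
        stack = cf.FrameStack(data=data, frame_rate=358.0, pixel_size=0.32)
        line = cf.EdgePolyline(np.column_stack(
            [np.linspace(2, 30, 5), np.full(5, 2.6)]))
        fit = cf.metachronal_wavelength(stack, line, n_segments=40,
                                        segment_len=8)
        assert fit.wavelength == pytest.approx(16.7, rel=0.02)

    def test_in_phase_movie_not_measurable(self):
        t = np.arange(256)[:, None, None] / 358.0
        data = 128.0 + 40.0 * np.sin(2 * np.pi * 9.0 * t) \
            * np.ones((1, 16, 100))
        stack = cf.FrameStack(data=data, frame_rate=358.0, pixel_size=0.32)
        line = cf.EdgePolyline(np.column_stack(
            [np.linspace(2, 30, 5), np.full(5, 2.6)]))
        with pytest.raises(WavelengthNotMeasurable):
            cf.metachronal_wavelength(stack, line, n_segments=40,
                                      segment_len=8)


class TestCiliaDensity:
    def test_recovers_generator_density(self, small_movie, small_spec):
        stack, truth = small_movie
        cz = small_spec.cilia_zone_mask()
        far = cf.band_mask(small_spec.edge_polyline, small_spec.shape,
                           small_spec.pixel_size, 18.0, side=-1)
        below = cf.band_mask(small_spec.edge_polyline, small_spec.shape,
                             small_spec.pixel_size, 2.0, side=+1)
        dens = cf.cilia_density(stack, cz, ~far & ~below)
        assert dens.rho_c == pytest.approx(truth.cilia_density, abs=0.01)
        assert dens.f_c == pytest.approx(1 - dens.rho_c)
        expected_dc = 0.2 * (1 - dens.rho_c) / dens.rho_c
        assert dens.d_c == pytest.approx(expected_dc)

    def test_extreme_densities(self):
        data = np.full((4, 40, 40), 100.0)
        data[:, :10, :] = 50.0                      # all darker
        stack = cf.FrameStack(data, 100.0, 1.0)
        cz = np.zeros((40, 40), bool)
        cz[:10] = True
        bg = np.zeros((40, 40), bool)
        bg[20:] = True
        dens = cf.cilia_density(stack, cz, bg)
        assert dens.rho_c == 1.0 and dens.d_c == 0.0
        data2 = np.full((4, 40, 40), 100.0)
        data2[:, :10, :] = 150.0                    # none darker
        dens2 = cf.cilia_density(cf.FrameStack(data2, 100.0, 1.0), cz, bg)
        assert dens2.rho_c == 0.0 and dens2.f_c == 1.0
        assert np.isnan(dens2.d_c)

    def test_invariant_under_affine_grey_rescaling(self, small_movie,
                                                   small_spec):
        stack, _ = small_movie
        cz = small_spec.cilia_zone_mask()
        far = cf.band_mask(small_spec.edge_polyline, small_spec.shape,
                           small_spec.pixel_size, 18.0, side=-1)
        bg = ~far & ~cf.band_mask(small_spec.edge_polyline, small_spec.shape,
                                  small_spec.pixel_size, 2.0, side=+1)
        base = cf.cilia_density(stack, cz, bg)
        rescaled = cf.FrameStack(0.5 * stack.data.astype(float) + 30.0,
                                 stack.frame_rate, stack.pixel_size)
        assert cf.cilia_density(rescaled, cz, bg).rho_c == base.rho_c

    def test_zone_validation(self, small_movie):
        stack, _ = small_movie
        zone = np.zeros(stack.data.shape[1:], bool)
        zone[:20] = True
        with pytest.raises(ValueError):
            cf.cilia_density(stack, zone, zone)     # overlap
        tiny = np.zeros_like(zone)
        tiny[0, :5] = True
        other = np.zeros_like(zone)
        other[-1] = True
        with pytest.raises(ValueError):
            cf.cilia_density(stack, tiny, other)    # < 100 px
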