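"""FIR auralization: design pipeline, latency, convolution, WAV IO."""

import numpy as np
import pytest

from uteroacoustics.auralize import (
    FIRFilter,
    FrequencyResponse,
    build_fir,
    convolve_audio,
    extend_response,
    read_wav,
    write_wav,
)

GRID = 1000.0 * 2.0 ** (np.arange(-67, 52) / 12.0)  # 12th-octave sweep grid


@pytest.fixture(scope="module")
def flat_fir():
    resp = FrequencyResponse(GRID, np.ones_like(GRID, dtype=complex))
    return build_fir(resp)


class TestDesign:
    def test_flat_response_gives_pure_delay(self, flat_fir):
        """Unit magnitude, zero phase: impulse response ~ delta at sample 200."""
        peak = int(np.argmax(np.abs(flat_fir.taps)))
        assert peak == 200
        assert np.abs(flat_fir.taps[peak]) > 0.9
        # off-peak energy is tiny (only the top-octave roll-off contributes)
        side = np.abs(flat_fir.taps).copy()
        side[peak - 4:peak + 5] = 0.0
        assert np.max(side) < 0.1

    def test_constant_group_delay(self, flat_fir):
        assert flat_fir.group_delay_samples(100.0, 10000.0) == pytest.approx(
            200.0, abs=0.01)

    def test_design_mse_verified_by_dft_oracle(self):
        """Achieved MSE matches a direct DFT evaluation of the taps against
        the spline-interpolated target."""
        from scipy.interpolate import CubicSpline

        # smooth, physically plausible transfer: gentle low-pass with a
        # resonant bump and smoothly accumulating phase lag
        mag = 1.0 / (1.0 + (GRID / 4000.0) ** 2) \
            + 0.5 * np.exp(-0.5 * ((np.log(GRID / 3000.0)) / 0.2) ** 2)
        ph = -GRID / 8000.0
        resp = FrequencyResponse(GRID, mag * np.exp(1j * ph))
        fir = build_fir(resp, mse_tol=1e-4)
        ext = extend_response(resp, 44100.0)
        fgrid = np.linspace(0.0, 22050.0, 16385)
        m_i = np.clip(CubicSpline(ext.frequencies, np.abs(ext.values))(fgrid), 0, None)
        p_i = CubicSpline(ext.frequencies, np.unwrap(np.angle(ext.values)))(fgrid)
        target = m_i * np.exp(1j * (p_i - 2 * np.pi * fgrid * 200 / 44100.0))
        target[0] = target[0].real
        target[-1] = target[-1].real
        H = np.fft.rfft(fir.taps, 2 * (16385 - 1))
        mse = np.sum(np.abs(H - target) ** 2) / np.sum(np.abs(target) ** 2)
        assert mse == pytest.approx(fir.design_mse, rel=1e-6)
        assert mse <= 1e-4

    def test_unreachable_tolerance_raises(self):
        rng = np.random.default_rng(3)
        resp = FrequencyResponse(
            GRID, 10 ** rng.uniform(-2, 1, GRID.size)
            * np.exp(1j * np.cumsum(rng.normal(0, 2.0, GRID.size))))
        with pytest.raises(RuntimeError, match="MSE"):
            build_fir(resp, mse_tol=1e-16, order_cap=512)

    def test_non_monotone_frequencies_rejected(self):
        with pytest.raises(ValueError):
            FrequencyResponse(np.array([100.0, 50.0, 200.0]), np.ones(3))

    def test_determinism(self):
        resp = FrequencyResponse(GRID, np.exp(-GRID / 5000.0) + 0j)
        a = build_fir(resp)
        b = build_fir(resp)
        assert np.array_equal(a.taps, b.taps)


class TestExtendResponse:
    def test_policies(self):
        resp = FrequencyResponse(GRID, np.full(GRID.size, 0.5 + 0.1j))
        ext = extend_response(resp, 44100.0)
        assert ext.frequencies[0] == 0.0
        assert ext.frequencies[-1] == pytest.approx(22050.0)
        assert np.all(np.diff(ext.frequencies) > 0)
        # magnitude at 0 Hz equals the lowest-band magnitude
        assert np.abs(ext.values[0]) == pytest.approx(np.abs(resp.values[0]))
        # in-band samples untouched
        sel = slice(1, 1 + GRID.size)
        np.testing.assert_allclose(ext.frequencies[sel], GRID)
        np.testing.assert_allclose(ext.values[sel], resp.values)
        # magnitude rolls off to (near) zero at Nyquist
        assert np.abs(ext.values[-1]) < 1e-10


class TestConvolution:
    def test_delta_filter_is_identity(self, rng):
        taps = np.zeros(32)
        taps[0] = 1.0
        fir = FIRFilter(taps=taps, fs=44100.0, order=32, design_mse=0.0,
                        delay_samples=0)
        x = rng.normal(size=500)
        y, meta = convolve_audio(fir, x, 44100.0, normalize=False)
        np.testing.assert_allclose(y[:500, 0], x, atol=1e-12)
        assert y.shape[0] == 500 + 32 - 1

    def test_linearity_before_normalization(self, flat_fir, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        ya, _ = convolve_audio(flat_fir, a, 44100.0, normalize=False)
        yb, _ = convolve_audio(flat_fir, b, 44100.0, normalize=False)
        yab, _ = convolve_audio(flat_fir, a + b, 44100.0, normalize=False)
        np.testing.assert_allclose(yab, ya + yb, atol=1e-10)

    def test_steady_state_tone_scaled_by_filter_magnitude(self):
        """A pure tone at a design frequency is scaled by |H(f)| within 1%."""
        f0, fs = 2000.0, 44100.0
        mag = 0.8 + 0.5 * np.sin(np.log(GRID))  # smooth non-flat magnitude
        resp = FrequencyResponse(GRID, mag.astype(complex))
        fir = build_fir(resp)
        t = np.arange(int(fs)) / fs
        tone = np.sin(2 * np.pi * f0 * t)
        out, _ = convolve_audio(fir, tone, fs, normalize=False)
        settled = out[20000:40000, 0]
        amp = (np.max(settled) - np.min(settled)) / 2.0
        assert amp == pytest.approx(np.abs(fir.frequency_response([f0]))[0], rel=0.01)

    def test_peak_normalization_and_gain_metadata(self, flat_fir, rng):
        x = 3.0 * rng.normal(size=400)
        y, meta = convolve_audio(flat_fir, x, 44100.0, normalize=True,
                                 peak_dbfs=-1.0)
        assert np.max(np.abs(y)) == pytest.approx(10 ** (-1 / 20), rel=1e-9)
        assert meta["gain"] != 1.0

    def test_sample_rate_mismatch(self, flat_fir, rng):
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="sample rate"):
            convolve_audio(flat_fir, x, 48000.0)
        y, _ = convolve_audio(flat_fir, x, 22050.0, allow_resample=True)
        assert y.shape[0] > 150  # upsampled then convolved

    def test_stereo_filtered_per_channel(self, flat_fir, rng):
        x = rng.normal(size=(300, 2))
        y, _ = convolve_audio(flat_fir, x, 44100.0, normalize=False)
        y0, _ = convolve_audio(flat_fir, x[:, 0], 44100.0, normalize=False)
        np.testing.assert_allclose(y[:, 0], y0[:, 0], atol=1e-12)


class TestIO:
    @pytest.mark.parametrize("subtype,atol", [("float32", 1e-7), ("pcm16", 1e-4)])
    def test_wav_round_trip(self, tmp_path, rng, subtype, atol):
        x = 0.8 * np.sin(2 * np.pi * 440.0 * np.arange(1000) / 44100.0)
        path = tmp_path / f"{subtype}.wav"
        write_wav(path, 44100.0, x, subtype=subtype)
        fs, back = read_wav(path)
        assert fs == 44100.0
        np.testing.assert_allclose(back[:, 0], x, atol=atol)

    def test_filter_save_load(self, tmp_path, flat_fir):
        path = tmp_path / "filter.txt"
        flat_fir.save(path)
        back = FIRFilter.load(path)
        np.testing.assert_allclose(back.taps, flat_fir.taps, rtol=1e-15)
        assert back.fs == flat_fir.fs
        assert back.order == flat_fir.order
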