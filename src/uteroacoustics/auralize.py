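"""Auralization: turn a barycentre frequency response into audible audio.

The sweep produces the complex transfer function from the incident plane
wave to the pressure at the uterus barycentre, sampled on the 12th-octave
grid.  To make that audible the response is (1) extended from the sweep
band to the full digital band [0, fs/2], (2) spline-interpolated (magnitude
and unwrapped phase separately) onto a dense uniform grid, (3) delayed by a
constant 200 samples so the phase is close to linear and the impulse
response causal, and (4) converted to a finite impulse response by a
least-squares fit whose order grows until the frequency-response MSE drops
below tolerance.  The resulting FIR filter is convolved with WAV audio.

Design grid: 16385 points over [0, fs/2] at fs = 44.1 kHz — exactly the
positive-frequency grid of a 32768-point DFT, so the unconstrained
least-squares problem is solved by an inverse real FFT, and truncating that
impulse response to a given order is the least-squares solution at that
order (orthogonality of the DFT basis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "FrequencyResponse",
    "FIRFilter",
    "build_fir",
    "extend_response",
    "convolve_audio",
    "read_wav",
    "write_wav",
]


@dataclass
class FrequencyResponse:
    """Complex transfer function samples on an ascending frequency grid."""

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=complex)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("need at least two frequency samples")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(v))):
            raise ValueError("non-finite frequency response")
        if v.shape != f.shape:
            raise ValueError("values and frequencies must have equal length")
        self.frequencies, self.values = f, v

    @classmethod
    def from_sweep_csv(cls, path) -> "FrequencyResponse":
        """Build from a sweep CSV (frequency_hz, barycentre_re/im_pa)."""
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["frequency_hz"].to_numpy(),
            df["barycentre_re_pa"].to_numpy() + 1j * df["barycentre_im_pa"].to_numpy(),
        )


@dataclass
class FIRFilter:
    """Causal FIR filter with design metadata."""

    taps: np.ndarray
    fs: float
    order: int
    design_mse: float
    delay_samples: int = 200
    metadata: dict = field(default_factory=dict)

    def frequency_response(self, frequencies: np.ndarray) -> np.ndarray:
        """Exact DTFT of the taps at the given frequencies (Hz)."""
        f = np.asarray(frequencies, dtype=float)
        n = np.arange(len(self.taps))
        return np.exp(-2j * np.pi * np.outer(f / self.fs, n)) @ self.taps

    def group_delay_samples(self, fmin: float = 100.0, fmax: float = 10000.0,
                            nfft: int = 32768) -> float:
        """Mean group delay (samples) over [fmin, fmax]."""
        from scipy.signal import group_delay

        freqs = np.fft.rfftfreq(nfft, d=1.0 / self.fs)
        sel = (freqs >= fmin) & (freqs <= fmax)
        w = 2.0 * np.pi * freqs[sel] / self.fs
        _, gd = group_delay((self.taps, [1.0]), w=w, fs=2 * np.pi)
        return float(np.mean(gd))

    def save(self, path) -> None:
        """Two-column text (sample index, coefficient) plus a YAML sidecar."""
        import yaml

        path = Path(path)
        np.savetxt(path, np.column_stack([np.arange(len(self.taps)), self.taps]),
                   fmt=["%d", "%.17g"], header="sample coefficient")
        meta = dict(self.metadata)
        meta.update(fs_hz=float(self.fs), order=int(self.order),
                    design_mse=float(self.design_mse),
                    delay_samples=int(self.delay_samples))
        path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def load(cls, path) -> "FIRFilter":
        import yaml

        path = Path(path)
        data = np.loadtxt(path)
        meta = yaml.safe_load(path.with_suffix(".meta.yaml").read_text())
        return cls(taps=data[:, 1], fs=meta["fs_hz"], order=meta["order"],
                   design_mse=meta["design_mse"],
                   delay_samples=meta.get("delay_samples", 200), metadata=meta)


def extend_response(resp: FrequencyResponse, fs: float = 44100.0,
                    rolloff_octaves: float = 1.0) -> FrequencyResponse:
    """Extend a band-limited response to cover [0, fs/2].

    Below the lowest sweep band the magnitude is held constant (the
    transfer characteristic is flat down into the infrasound range); above
    the highest band it rolls off smoothly (raised-cosine over
    ``rolloff_octaves``) to zero at fs/2; the phase continues linearly in
    frequency at the boundary slopes.  In-band samples are untouched.
    """
    f, v = resp.frequencies, resp.values
    nyq = fs / 2.0
    if f[-1] >= nyq:
        keep = f < nyq
        f, v = f[keep], v[keep]
    mag = np.abs(v)
    ph = np.unwrap(np.angle(v))

    lo_f = [0.0] if f[0] > 0 else []
    lo_mag = [mag[0]] if lo_f else []
    slope_lo = (ph[1] - ph[0]) / (f[1] - f[0])
    lo_ph = [ph[0] - slope_lo * f[0]] if lo_f else []

    hi_f, hi_mag, hi_ph = [], [], []
    slope_hi = (ph[-1] - ph[-2]) / (f[-1] - f[-2])
    # raised-cosine roll-off completing at Nyquist (or after rolloff_octaves,
    # whichever comes first)
    span = min(rolloff_octaves, np.log2(nyq / f[-1]))
    extra = np.linspace(f[-1], nyq, 16)[1:]
    for fe in extra:
        frac = min(np.log2(fe / f[-1]) / span, 1.0)
        hi_f.append(fe)
        hi_mag.append(mag[-1] * 0.5 * (1.0 + np.cos(np.pi * frac)))
        hi_ph.append(ph[-1] + slope_hi * (fe - f[-1]))

    fx = np.concatenate([lo_f, f, hi_f])
    magx = np.concatenate([lo_mag, mag, hi_mag])
    phx = np.concatenate([lo_ph, ph, hi_ph])
    return FrequencyResponse(fx, magx * np.exp(1j * phx))


def build_fir(
    resp: FrequencyResponse,
    fs: float = 44100.0,
    n_interp: int = 16385,
    delay_samples: int = 200,
    mse_tol: float = 1e-4,
    order_cap: int = 8192,
) -> FIRFilter:
    """Synthesize a causal FIR filter from a complex frequency response.

    Magnitude and unwrapped phase are cubic-spline interpolated onto
    ``n_interp`` uniform points over [0, fs/2] (unwrapping happens on the
    coarse sweep grid, where it is stable); a linear phase
    ``exp(-i 2 pi f delay / fs)`` is multiplied in; the impulse response of
    the dense target is obtained by inverse real FFT and truncated at
    increasing orders until the relative frequency-response MSE is at most
    ``mse_tol``.

    Raises if the tolerance is unreachable at ``order_cap``, reporting the
    achieved MSE.
    """
    if resp.frequencies[0] > 0.0 or resp.frequencies[-1] < fs / 2.0:
        resp = extend_response(resp, fs)
    mag = np.abs(resp.values)
    ph = np.unwrap(np.angle(resp.values))
    fgrid = np.linspace(0.0, fs / 2.0, n_interp)
    mag_i = np.clip(CubicSpline(resp.frequencies, mag)(fgrid), 0.0, None)
    ph_i = CubicSpline(resp.frequencies, ph)(fgrid)
    target = mag_i * np.exp(1j * (ph_i - 2.0 * np.pi * fgrid * delay_samples / fs))
    # force real DC and Nyquist samples (real impulse response)
    target[0] = np.real(target[0])
    target[-1] = np.real(target[-1])

    nfft = 2 * (n_interp - 1)
    h_full = np.fft.irfft(target, nfft)
    denom = float(np.sum(np.abs(target) ** 2))

    order = max(4 * delay_samples, 256)
    best_mse = np.inf
    while True:
        order = min(order, order_cap)
        h = h_full[:order]
        H = np.fft.rfft(h, nfft)
        mse = float(np.sum(np.abs(H - target) ** 2)) / denom
        best_mse = min(best_mse, mse)
        if mse <= mse_tol:
            break
        if order >= order_cap:
            raise RuntimeError(
                f"FIR design MSE {best_mse:.3e} above tolerance {mse_tol:.1e} "
                f"at order cap {order_cap}"
            )
        order *= 2
    return FIRFilter(
        taps=h.copy(), fs=float(fs), order=int(order), design_mse=mse,
        delay_samples=int(delay_samples),
        metadata={"n_interp": int(n_interp), "mse_tol": float(mse_tol)},
    )


# ---------------------------------------------------------------------------
# audio IO and convolution
# ---------------------------------------------------------------------------

def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a WAV file to float64 samples in [-1, 1]; (fs, (n, channels))."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128.0) / 128.0
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    return float(fs), data


def write_wav(path, fs: float, data: np.ndarray, subtype: str = "float32") -> None:
    """Write float samples as 32-bit float or 16-bit PCM WAV."""
    from scipy.io import wavfile

    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1:
        data = data.T
    if subtype == "float32":
        wavfile.write(path, int(fs), data.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(data, -1.0, 1.0 - 1.0 / 32768.0)
        wavfile.write(path, int(fs), np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def convolve_audio(
    fir: FIRFilter,
    audio: np.ndarray,
    fs: float,
    normalize: bool = True,
    peak_dbfs: float = -1.0,
    allow_resample: bool = False,
) -> tuple[np.ndarray, dict]:
    """Linear convolution of (multi-channel) audio with the filter.

    Channels are filtered independently with the same impulse response.
    Output length is ``n + len(taps) - 1``.  With ``normalize`` the output
    is peak-normalised to ``peak_dbfs`` and the applied gain recorded in
    the returned metadata; raw (un-normalised) output is linear in the
    input.  A sample-rate mismatch raises unless ``allow_resample``.
    """
    from scipy.signal import fftconvolve, resample_poly

    audio = np.atleast_2d(np.asarray(audio, dtype=float))
    if audio.shape[0] < audio.shape[1]:
        audio = audio.T
    if not np.isclose(fs, fir.fs):
        if not allow_resample:
            raise ValueError(
                f"audio sample rate {fs} Hz != filter rate {fir.fs} Hz "
                f"(pass allow_resample=True to resample)"
            )
        from fractions import Fraction

        frac = Fraction(int(round(fir.fs)), int(round(fs))).limit_denominator(1000)
        audio = resample_poly(audio, frac.numerator, frac.denominator, axis=0)
    out = np.stack(
        [fftconvolve(audio[:, c], fir.taps) for c in range(audio.shape[1])],
        axis=1,
    )
    meta = {"gain": 1.0, "fs_hz": float(fir.fs)}
    if normalize:
        peak = float(np.max(np.abs(out)))
        if peak > 0:
            gain = 10.0 ** (peak_dbfs / 20.0) / peak
            out = out * gain
            meta["gain"] = gain
    return out, meta
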