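"""Exposure metrics and the 12th-octave sweep protocol.

Sound pressure levels are reported in dB re 1 Pa.  Because the incident
plane wave has unit amplitude (1 Pa), 0 dB means "equal to the incident
wave"; positive values indicate amplification by scattering and modal
build-up.

Two spatial statistics summarise the field sampled on a Cartesian grid of
N points inside a region:

* impact SPL, ``L_RMS = 20 log10 sqrt( (1/N) sum_i |p_i|^2 )`` — the
  ISO 10052 section 3.7 spatial root-mean-square of pressure magnitudes,
  an average exposure measure insensitive to phase cancellation;
* l-infinity SPL, ``L_linf = 20 log10 max_i |p_i|`` — the worst-case local
  exposure.

``L_linf >= L_RMS`` always, with equality only for uniform magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BandGrid",
    "twelfth_octave_grid",
    "impact_spl",
    "linf_spl",
    "SweepResult",
]


@dataclass(frozen=True)
class BandGrid:
    """Geometric grid of band centre frequencies, ratio 2**(1/12)."""

    frequencies: np.ndarray
    reference: float = 1000.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1D array")
        ratios = f[1:] / f[:-1]
        if f.size > 1 and not np.allclose(ratios, 2.0 ** (1.0 / 12.0), rtol=1e-12):
            raise ValueError("adjacent centre frequencies must have ratio 2**(1/12)")
        if not np.any(np.isclose(f, self.reference, rtol=1e-12)):
            raise ValueError(
                f"grid must contain the reference frequency {self.reference} Hz"
            )

    def __len__(self) -> int:
        return int(self.frequencies.size)

    def __iter__(self):
        return iter(self.frequencies)

    def nearest_band(self, f: float) -> float:
        """Centre frequency of the band closest (in log-frequency) to ``f``."""
        i = int(np.argmin(np.abs(np.log(self.frequencies) - np.log(f))))
        return float(self.frequencies[i])


def twelfth_octave_grid(
    fmin: float = 20.0, fmax: float = 20000.0, ref: float = 1000.0
) -> BandGrid:
    """Band centres ``ref * 2**(n/12)`` for all integers n with centres in
    ``[fmin, fmax]`` (inclusive).

    The default audio-range grid anchored at 1 kHz spans 20.2 Hz to
    19.0 kHz (119 bands).
    """
    if not 0 < fmin < ref <= fmax:
        raise ValueError(f"require 0 < fmin < ref <= fmax, got {fmin}, {ref}, {fmax}")
    step = 2.0 ** (1.0 / 12.0)
    n_lo = int(np.ceil(np.log(fmin / ref) / np.log(step) - 1e-12))
    n_hi = int(np.floor(np.log(fmax / ref) / np.log(step) + 1e-12))
    n = np.arange(n_lo, n_hi + 1)
    return BandGrid(frequencies=ref * step ** n.astype(float), reference=ref)


def impact_spl(pressures: np.ndarray) -> float:
    """Impact SPL: dB level of the spatial RMS of pressure magnitudes.

    Returns ``-inf`` for an identically zero field.
    """
    p = np.asarray(pressures)
    if p.size == 0:
        raise ValueError("impact_spl requires at least one pressure sample")
    ms = float(np.mean(np.abs(p) ** 2))
    if ms == 0.0:
        return -np.inf
    return float(10.0 * np.log10(ms))


def linf_spl(pressures: np.ndarray) -> float:
    """l-infinity SPL: dB level of the maximum pressure magnitude."""
    p = np.asarray(pressures)
    if p.size == 0:
        raise ValueError("linf_spl requires at least one pressure sample")
    mx = float(np.max(np.abs(p)))
    if mx == 0.0:
        return -np.inf
    return float(20.0 * np.log10(mx))


@dataclass
class SweepResult:
    """Per-band exposure metrics for one region of a phantom.

    ``spl_rms`` / ``spl_linf`` are dB re 1 Pa; ``barycentre_pressure`` is the
    complex pressure (Pa) at the region's volume centroid, which carries the
    magnitude and phase information needed for FIR auralization.  Bands where
    the solver failed are flagged in ``failed`` and carry NaN metrics.
    """

    frequencies: np.ndarray
    spl_rms: np.ndarray
    spl_linf: np.ndarray
    barycentre_pressure: np.ndarray
    region: str = "uterus"
    metadata: dict = field(default_factory=dict)
    failed: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.frequencies)
        for name in ("spl_rms", "spl_linf", "barycentre_pressure"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of frequencies")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": np.asarray(self.frequencies, dtype=float),
                "spl_rms_db": np.asarray(self.spl_rms, dtype=float),
                "spl_linf_db": np.asarray(self.spl_linf, dtype=float),
                "barycentre_re_pa": np.real(self.barycentre_pressure),
                "barycentre_im_pa": np.imag(self.barycentre_pressure),
            }
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the sweep table; optionally a YAML metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            import yaml

            meta = dict(self.metadata)
            meta.setdefault("region", self.region)
            meta.setdefault("failed_bands_hz", [float(f) for f in self.failed])
            meta.setdefault("determinism", "seed-free; identical inputs give identical output")
            path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def from_csv(cls, path: str | Path, region: str = "uterus") -> "SweepResult":
        df = pd.read_csv(path)
        return cls(
            frequencies=df["frequency_hz"].to_numpy(),
            spl_rms=df["spl_rms_db"].to_numpy(),
            spl_linf=df["spl_linf_db"].to_numpy(),
            barycentre_pressure=(
                df["barycentre_re_pa"].to_numpy() + 1j * df["barycentre_im_pa"].to_numpy()
            ),
            region=region,
        )


def find_resonance_peaks(
    frequencies: np.ndarray, spl_db: np.ndarray, prominence_db: float = 3.0
) -> np.ndarray:
    """Frequencies (Hz) of local maxima of an SPL curve, by prominence.

    Uses :func:`scipy.signal.find_peaks`; returns peak centre frequencies
    ordered by descending prominence.
    """
    from scipy.signal import find_peaks

    spl = np.asarray(spl_db, dtype=float)
    idx, props = find_peaks(spl, prominence=prominence_db)
    order = np.argsort(props["prominences"])[::-1]
    return np.asarray(frequencies, dtype=float)[idx[order]]


def highlight_resonances(
    frequencies: np.ndarray, spl_db: np.ndarray, n: int = 2,
    prominence_db: float = 3.0,
) -> np.ndarray:
    """The ``n`` most prominent resonance peaks, ascending in frequency.

    Selection happens on the band-sampled curve; because the underlying
    cavity resonances can be much narrower than a 12th-octave band, the
    sampled peak positions and heights depend on how band centres align
    with the resonances.
    """
    peaks = find_resonance_peaks(frequencies, spl_db, prominence_db)[:n]
    return np.sort(peaks)
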