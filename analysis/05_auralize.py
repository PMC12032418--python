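#!/usr/bin/env python
"""Render the in-utero listening impression for the validation phantom.

Takes the barycentre frequency response of the high-attenuation sweep
(analysis/02), designs the causal least-squares FIR filter (44.1 kHz,
16385 design points, 200-sample delay), and convolves a synthesized
reference soundscape (tone cluster + noise bursts standing in for the
study's licensed audio assets).  The filter taps go to
results/barycentre_filter.txt; audio WAVs go to scratch/ (regenerate with
this script).
"""

from pathlib import Path

import numpy as np

from uteroacoustics.auralize import (
    FrequencyResponse,
    build_fir,
    convolve_audio,
    write_wav,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
OUT.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)

sweep_csv = OUT / "sweep_high_attenuation.csv"
if not sweep_csv.exists():
    raise SystemExit("run analysis/02_exposure_sweeps.py first "
                     f"(missing {sweep_csv})")

resp = FrequencyResponse.from_sweep_csv(sweep_csv)
fir = build_fir(resp, fs=44100.0, n_interp=16385, delay_samples=200)
fir.save(OUT / "barycentre_filter.txt")
print(f"FIR filter: order {fir.order}, design MSE {fir.design_mse:.2e}, "
      f"group delay {fir.group_delay_samples():.1f} samples")

# synthetic reference soundscape: rumble, speech-band tones, applause-like noise
fs = 44100.0
t = np.arange(int(4 * fs)) / fs
rng = np.random.default_rng(1234)  # demo-signal synthesis only
sound = (0.3 * np.sin(2 * np.pi * 80.0 * t) * (t < 1.5)
         + 0.2 * np.sin(2 * np.pi * 440.0 * t) * ((t > 1.0) & (t < 2.5))
         + 0.15 * np.sin(2 * np.pi * 1800.0 * t) * ((t > 2.0) & (t < 3.0))
         + 0.1 * rng.normal(size=t.size) * (t > 2.8))
write_wav(SCRATCH / "reference_soundscape.wav", fs, sound)
filtered, meta = convolve_audio(fir, sound, fs)
write_wav(SCRATCH / "in_utero_soundscape.wav", fir.fs, filtered)
print(f"wrote scratch/reference_soundscape.wav and "
      f"scratch/in_utero_soundscape.wav (normalisation gain {meta['gain']:.3g})")
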