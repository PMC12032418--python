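#!/usr/bin/env python
"""Pressure-magnitude maps through the validation phantom.

Evaluates the analytical layered-sphere field on the x-y plane through the
centre at the resonance frequencies found by the sweep driver (3 kHz and
8.5 kHz in a continuous scan) and at 20 kHz, the top of the audio range,
showing the transition from simple shielding/focusing to dense multiple
scattering.  Writes results/map_<f>.csv (x, y, z, SPL re 1 Pa).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from uteroacoustics.layered_sphere import LayeredSphereModel, pressure_field, solve_modal
from uteroacoustics.media import AIR, get_medium
from uteroacoustics.sweeps import plane_grid

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

model = LayeredSphereModel(
    radii=(0.25, 0.15),
    media=(AIR, get_medium("Abdominal tissue"), get_medium("Amniotic fluid")),
    direction=(1.0, 0.0, 0.0),
)

for f in (3000.0, 8500.0, 20000.0):
    pts = plane_grid("z", 0.0, 0.35, 81)
    p = pressure_field(solve_modal(model, f), pts)
    with np.errstate(divide="ignore"):
        spl = 20.0 * np.log10(np.abs(p))
    df = pd.DataFrame({"x_m": pts[:, 0], "y_m": pts[:, 1], "z_m": pts[:, 2],
                       "spl_db": spl})
    path = OUT / f"map_{int(f)}hz.csv"
    df.to_csv(path, index=False)
    inside = np.linalg.norm(pts, axis=1) < 0.15
    print(f"{f / 1000:5.1f} kHz: interior SPL range "
          f"[{spl[inside].min():7.2f}, {spl[inside].max():6.2f}] dB re 1 Pa; "
          f"wrote {path.name}")
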