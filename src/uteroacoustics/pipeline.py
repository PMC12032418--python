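"""Run configuration and the canned end-to-end experiments.

Thin orchestration over the library: a :class:`RunConfig` (YAML-round-
trippable) names a phantom, band grid, solver and evaluation-grid policy;
the ``cmd_*`` functions execute sweeps, the two-sphere validation, field
maps and auralization, writing CSV tables plus metadata sidecars.  All
commands are deterministic given their configuration — there is no
randomness anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from uteroacoustics import media as media_mod
from uteroacoustics.media import Medium
from uteroacoustics.metrics import twelfth_octave_grid
from uteroacoustics.phantom import (
    interior_grid,
    nested_sphere_phantom,
    nested_three_region_phantom,
    volume_centroid,
)
from uteroacoustics.sweeps import plane_grid, run_sweep, validate_spheres

__all__ = [
    "RunConfig",
    "cmd_sweep",
    "cmd_validate_spheres",
    "cmd_map",
    "cmd_auralize",
]


@dataclass
class RunConfig:
    """Declarative description of one experiment.

    ``phantom_type`` is "nested_spheres" or "three_region"; media are named
    by their material-library entries (or "air").  ``solver`` is "analytic"
    or "bem"; ``max_frequency`` caps BEM sweeps (the dense solver is
    desk-scale; the analytic solver covers the full audio range).
    """

    phantom_type: str = "nested_spheres"
    outer_radius: float = 0.25
    inner_radius: float = 0.15
    media: dict = field(default_factory=lambda: {
        "exterior": "Air",
        "abdomen": "Abdominal tissue",
        "uterus": "Amniotic fluid",
    })
    spine_semi_axes: tuple = (0.02, 0.02, 0.18)
    spine_center: tuple = (-0.2, 0.0, 0.0)
    elements_per_wavelength: float = 5.0
    fmin: float = 20.0
    fmax: float = 20000.0
    reference_frequency: float = 1000.0
    solver: str = "analytic"
    tol: float = 1e-4
    max_iter: int = 2000
    max_frequency: float = 2000.0
    grid_spacing: float | None = None
    solid_angle_threshold: float = 0.5
    direction: tuple = (1.0, 0.0, 0.0)
    amplitude: float = 1.0
    region: str = "uterus"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.phantom_type not in ("nested_spheres", "three_region"):
            raise ValueError(f"unknown phantom type {self.phantom_type!r}")
        if self.solver not in ("analytic", "bem"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.solver == "analytic" and self.phantom_type != "nested_spheres":
            raise ValueError("analytic solver requires the concentric-sphere phantom")
        for key in ("exterior", "abdomen", "uterus"):
            if key not in self.media:
                raise ValueError(f"media must name {key!r}")
            self.resolve_medium(self.media[key])  # raises for unknown names

    def resolve_medium(self, name: str) -> Medium:
        if name.lower() == "air":
            return media_mod.AIR
        return media_mod.get_medium(name)

    def media_map(self) -> dict:
        keys = ["exterior", "abdomen", "uterus"]
        if self.phantom_type == "three_region":
            keys.append("spine")
        return {k: self.resolve_medium(self.media[k]) for k in keys}

    def phantom_builder(self):
        """Callable f -> NestedTopology implementing the per-band mesh rule."""
        mm = self.media_map()

        def build(f: float):
            if self.phantom_type == "nested_spheres":
                return nested_sphere_phantom(
                    self.outer_radius, self.inner_radius,
                    self.elements_per_wavelength, f, media=mm)
            return nested_three_region_phantom(
                self.outer_radius, self.inner_radius, self.spine_semi_axes,
                self.spine_center, self.elements_per_wavelength, f, media=mm)

        return build

    def band_grid(self):
        fmax = self.fmax
        if self.solver == "bem":
            fmax = min(fmax, self.max_frequency)
        return twelfth_octave_grid(self.fmin, fmax, self.reference_frequency)

    # -- round trip ---------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["spine_semi_axes"] = list(d["spine_semi_axes"])
        d["spine_center"] = list(d["spine_center"])
        d["direction"] = list(d["direction"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("spine_semi_axes", "spine_center", "direction"):
            if key in d:
                d[key] = tuple(d[key])
        known = set(cls.__dataclass_fields__)
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def cmd_sweep(config: RunConfig, name: str = "sweep") -> Path:
    """Run the configured frequency sweep; write CSV + metadata sidecar."""
    out = _outdir(config)
    result = run_sweep(
        config.phantom_builder(),
        config.band_grid(),
        solver=config.solver,
        region=config.region,
        direction=config.direction,
        amplitude=config.amplitude,
        spacing=config.grid_spacing,
        solid_angle_threshold=config.solid_angle_threshold,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    result.metadata["config"] = asdict(config)
    path = out / f"{name}.csv"
    result.to_csv(path)
    return path


def cmd_validate_spheres(config: RunConfig, name: str = "validation") -> Path:
    """BEM vs analytic benchmark; writes the per-band table and summary."""
    out = _outdir(config)
    df, summary = validate_spheres(
        outer_radius=config.outer_radius,
        inner_radius=config.inner_radius,
        elements_per_wavelength=config.elements_per_wavelength,
        fmax=min(config.max_frequency, config.fmax),
        media=config.media_map(),
        direction=config.direction,
        spacing=config.grid_spacing,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    path = out / f"{name}.csv"
    df.to_csv(path, index=False)
    path.with_suffix(".summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    return path


def cmd_map(config: RunConfig, frequency: float, axis: str = "z",
            offset: float | None = None, half_extent: float | None = None,
            resolution: int = 61, name: str = "map") -> Path:
    """SPL field map on an axis-aligned plane through the region barycentre."""
    out = _outdir(config)
    builder = config.phantom_builder()
    topo = builder(frequency)
    if offset is None:
        bc = volume_centroid(topo.surfaces[topo.surface_index(config.region)])
        offset = float(bc["xyz".index(axis.lower())])
    if half_extent is None:
        half_extent = 1.2 * config.outer_radius
    pts = plane_grid(axis, offset, half_extent, resolution)

    if config.solver == "analytic":
        from uteroacoustics.layered_sphere import pressure_field, solve_modal
        from uteroacoustics.phantom import signed_solid_angles
        from uteroacoustics.sweeps import sphere_model_from_topology

        model = sphere_model_from_topology(topo, config.direction, config.amplitude)
        p = pressure_field(solve_modal(model, frequency), pts)
        near = np.zeros(len(pts), dtype=bool)
        for s in topo.surfaces:
            near |= np.abs(signed_solid_angles(s, pts)).max(axis=1) > \
                config.solid_angle_threshold
    else:
        from uteroacoustics.bem import PlaneWave, TransmissionProblem, assemble, \
            evaluate_field, solve

        prob = TransmissionProblem(topo, frequency,
                                   PlaneWave(config.direction, config.amplitude))
        sol = solve(assemble(prob), tol=config.tol, max_iter=config.max_iter)
        fv = evaluate_field(sol, pts,
                            exclusion_threshold=config.solid_angle_threshold)
        p, near = fv.pressure, fv.near_surface

    with np.errstate(divide="ignore"):
        spl = 20.0 * np.log10(np.abs(p))
    df = pd.DataFrame({
        "x_m": pts[:, 0], "y_m": pts[:, 1], "z_m": pts[:, 2],
        "spl_db": spl, "pressure_re_pa": p.real, "pressure_im_pa": p.imag,
        "near_surface": near,
    })
    path = out / f"{name}.csv"
    df.to_csv(path, index=False)
    return path


def cmd_auralize(config: RunConfig, response_csv, wav_in, wav_out,
                 mse_tol: float = 1e-4) -> Path:
    """Design the barycentre FIR filter from a sweep CSV and filter audio."""
    from uteroacoustics.auralize import (
        FrequencyResponse,
        build_fir,
        convolve_audio,
        read_wav,
        write_wav,
    )

    resp = FrequencyResponse.from_sweep_csv(response_csv)
    fir = build_fir(resp, mse_tol=mse_tol)
    fs, audio = read_wav(wav_in)
    out, meta = convolve_audio(fir, audio, fs, allow_resample=True)
    write_wav(wav_out, fir.fs, out)
    fir.metadata.update(meta)
    fir.save(Path(wav_out).with_suffix(".fir.txt"))
    return Path(wav_out)
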