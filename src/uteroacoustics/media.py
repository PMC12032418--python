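"""Tissue acoustic material models.

Each anatomical region is treated as a homogeneous fluid characterised by an
equilibrium sound speed ``c0`` (m/s), a density ``rho`` (kg/m^3) and a
power-law attenuation ``alpha(f) = alpha_ref * (f / 1 MHz)**b`` in Np/m, with
``b = 1`` for soft tissue and bone and ``b = 2`` for water-like amniotic
fluid.  Attenuation coefficients for soft tissue at audio frequencies are
derived from quasi-static viscoelastic measurements through the loss tangent
of the complex bulk modulus (:func:`alpha_from_loss_tangent`).

Time convention: fields oscillate as ``exp(-i omega t)``, so a lossy medium
must have ``Im k > 0`` for a plane wave ``exp(i k x)`` to decay along its
propagation direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "Medium",
    "ViscoelasticSpec",
    "alpha_from_loss_tangent",
    "power_law_alpha",
    "complex_wavenumber",
    "table1_library",
    "AIR",
    "load_media",
    "save_media",
]

#: Reference frequency (Hz) at which ``alpha_ref`` is quoted.
F_REF = 1.0e6


@dataclass(frozen=True)
class Medium:
    """Homogeneous acoustic medium with power-law attenuation.

    Parameters
    ----------
    name:
        Human-readable label ("Abdominal tissue", ...).
    c0:
        Equilibrium speed of sound, m/s.  Must be positive.
    rho:
        Mass density, kg/m^3.  Must be positive.
    alpha_ref:
        Attenuation coefficient at 1 MHz, Np/m.  Non-negative.
    power_b:
        Attenuation power-law exponent; 1 (linear, soft tissue/bone) or
        2 (quadratic, water-like fluids).
    """

    name: str
    c0: float
    rho: float
    alpha_ref: float = 0.0
    power_b: int = 1

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"{self.name}: c0 must be positive, got {self.c0}")
        if self.rho <= 0:
            raise ValueError(f"{self.name}: rho must be positive, got {self.rho}")
        if self.alpha_ref < 0:
            raise ValueError(f"{self.name}: alpha_ref must be >= 0, got {self.alpha_ref}")
        if self.power_b not in (1, 2):
            raise ValueError(f"{self.name}: power_b must be 1 or 2, got {self.power_b}")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance ``rho * c0`` (rayl)."""
        return self.rho * self.c0

    def wavelength(self, f: float) -> float:
        """Wavelength ``c0 / f`` in metres at frequency ``f`` (Hz)."""
        if f <= 0:
            raise ValueError(f"frequency must be positive, got {f}")
        return self.c0 / f


@dataclass(frozen=True)
class ViscoelasticSpec:
    """Quasi-static viscoelastic description of a soft tissue.

    The complex longitudinal sound speed is
    ``c_L = c0 * sqrt(1 + i tan(delta))`` where ``tan(delta)`` is the loss
    tangent of the complex bulk modulus (Young's modulus approximated by the
    bulk modulus in the absence of shear waves).
    """

    c0: float
    tan_delta: float
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if not 0.0 <= self.tan_delta < 1.0:
            raise ValueError(f"tan_delta must be in [0, 1), got {self.tan_delta}")

    @property
    def delta(self) -> float:
        """Loss angle ``arctan(tan_delta)`` in radians."""
        return math.atan(self.tan_delta)


def alpha_from_loss_tangent(spec: ViscoelasticSpec, f: float) -> float:
    """Attenuation coefficient (Np/m) of a loss-tangent viscoelastic medium.

    With loss angle ``delta = arctan(tan_delta)`` the attenuation is

        alpha(f) = (2 pi sqrt(cos delta) / c0) * sin(delta / 2) * f,

    exactly linear in frequency.

    Parameters
    ----------
    spec:
        Viscoelastic description of the medium.
    f:
        Frequency in Hz, must be non-negative.
    """
    if f < 0:
        raise ValueError(f"frequency must be non-negative, got {f}")
    d = spec.delta
    return 2.0 * math.pi * math.sqrt(math.cos(d)) / spec.c0 * math.sin(d / 2.0) * f


def power_law_alpha(medium: Medium, f: float) -> float:
    """Power-law attenuation ``alpha_ref * (f / 1 MHz)**power_b`` in Np/m."""
    if f < 0:
        raise ValueError(f"frequency must be non-negative, got {f}")
    return medium.alpha_ref * (f / F_REF) ** medium.power_b


def complex_wavenumber(medium: Medium, f: float) -> complex:
    """Complex wavenumber at frequency ``f`` (Hz).

    Returns ``2 pi f / c0 + i alpha(f)``.  The positive imaginary part makes
    a plane wave ``exp(i k x)`` decay along +x under the ``exp(-i omega t)``
    time convention, i.e. lossy media dissipate rather than amplify.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return 2.0 * math.pi * f / medium.c0 + 1j * power_law_alpha(medium, f)


def wavenumber_viscoelastic(spec: ViscoelasticSpec, f: float) -> complex:
    """Complex wavenumber of a loss-tangent medium, ``omega / c_L``.

    ``c_L = c0 / sqrt(cos delta) * exp(i delta / 2)`` gives

        k = (omega sqrt(cos delta) / c0) * (cos(delta/2) + i sin(delta/2)),

    with the imaginary sign chosen for decay (see module docstring).  For
    small ``delta`` this reduces to ``(omega / c0) * (1 + i delta / 2)``.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    d = spec.delta
    omega = 2.0 * math.pi * f
    mag = omega * math.sqrt(math.cos(d)) / spec.c0
    return mag * (math.cos(d / 2.0) + 1j * math.sin(d / 2.0))


#: Exterior medium.  Standard dry-air values at ~20 C; attenuation in air is
#: negligible over metre-scale paths at audio frequencies.
AIR = Medium("Air", c0=343.0, rho=1.2, alpha_ref=0.0, power_b=1)


def table1_library() -> list[Medium]:
    """The anatomical material library plus the air exterior.

    Four tissue groups (abdominal soft tissue, spine bone, uterine tissue
    as the high-attenuation uterus model, amniotic fluid as the
    low-attenuation model) and lossless air.
    """
    return [
        Medium("Abdominal tissue", c0=1489.0, rho=950.0, alpha_ref=0.1, power_b=1),
        Medium("Spine bone", c0=4020.0, rho=2700.0, alpha_ref=0.2, power_b=1),
        Medium("Uterine tissue", c0=1500.0, rho=1000.0, alpha_ref=585.3, power_b=1),
        Medium("Amniotic fluid", c0=1500.0, rho=1000.0, alpha_ref=15.0e-3, power_b=2),
        AIR,
    ]


def get_medium(name: str) -> Medium:
    """Look up a medium from :func:`table1_library` by (case-insensitive) name."""
    for m in table1_library():
        if m.name.lower() == name.lower():
            return m
    raise KeyError(f"unknown medium {name!r}; known: "
                   f"{[m.name for m in table1_library()]}")


def save_media(media: list[Medium], path: str | Path) -> None:
    """Write a material table to a YAML file.

    Keys per entry: ``name, c0, rho, alpha_ref_1MHz, power_b``.
    """
    rows = [
        {
            "name": m.name,
            "c0": float(m.c0),
            "rho": float(m.rho),
            "alpha_ref_1MHz": float(m.alpha_ref),
            "power_b": int(m.power_b),
        }
        for m in media
    ]
    Path(path).write_text(yaml.safe_dump({"media": rows}, sort_keys=False))


def load_media(path: str | Path) -> list[Medium]:
    """Read a material table written by :func:`save_media`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "media" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'media' list")
    return [
        Medium(
            name=row["name"],
            c0=float(row["c0"]),
            rho=float(row["rho"]),
            alpha_ref=float(row["alpha_ref_1MHz"]),
            power_b=int(row["power_b"]),
        )
        for row in data["media"]
    ]
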