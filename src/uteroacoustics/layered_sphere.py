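"""Plane-wave transmission through concentric layered spheres.

Analytical reference solution for the validation phantom: a plane wave in
the exterior medium strikes nested concentric spherical layers, and the
field in every region is expanded in spherical harmonics,

    p(r, theta) = sum_n  i^n (2n+1) P_n(cos theta)
                  [ A_n^m j_n(k_m r) + B_n^m h_n^(1)(k_m r) ],

with theta measured from the propagation direction (the problem is
axisymmetric).  The exterior region has ``A_n = 1`` (incident wave of unit
amplitude) and unknown outgoing coefficient ``B_n``; intermediate layers
carry both regular and outgoing parts; the core is regular only.  At each
interface the pressure and the normal velocity ``(1/rho) dp/dr`` are
continuous, giving a small linear system per modal order.

Used as the independent oracle against which the boundary-element solver is
validated, and as the fast solver for full-audio-range sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn, spherical_yn

from uteroacoustics.media import Medium, complex_wavenumber

__all__ = [
    "LayeredSphereModel",
    "ModalSolution",
    "solve_modal",
    "pressure_field",
    "sweep_inner_sphere",
]


def _sph_h1(n: int, z: np.ndarray, derivative: bool = False) -> np.ndarray:
    return spherical_jn(n, z, derivative) + 1j * spherical_yn(n, z, derivative)


@dataclass(frozen=True)
class LayeredSphereModel:
    """Concentric layered sphere with a plane-wave excitation.

    ``radii`` are strictly decreasing interface radii (m); ``media`` lists
    the exterior medium followed by one medium per layer, innermost last
    (``len(media) == len(radii) + 1``).  The incident wave is
    ``amplitude * exp(i k0 direction . x)``.
    """

    radii: tuple
    media: tuple
    direction: tuple = (1.0, 0.0, 0.0)
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) >= 0):
            raise ValueError("radii must be positive and strictly decreasing")
        if len(self.media) != r.size + 1:
            raise ValueError("need exactly one medium per region (radii count + 1)")
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0):
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "radii", tuple(float(x) for x in r))
        object.__setattr__(self, "media", tuple(self.media))
        object.__setattr__(self, "direction", tuple(float(x) for x in d))

    @property
    def n_regions(self) -> int:
        return len(self.media)

    def region_of(self, r: np.ndarray) -> np.ndarray:
        """Region index per radius; points exactly on an interface are
        assigned to the inner side."""
        r = np.asarray(r, dtype=float)
        return np.searchsorted(-np.asarray(self.radii), -r, side="right")


@dataclass
class ModalSolution:
    """Per-order radial coefficients in every region at one frequency."""

    model: LayeredSphereModel
    f: float
    wavenumbers: np.ndarray        # complex, per region
    regular: np.ndarray            # (n_regions, N+1) coefficients of j_n
    outgoing: np.ndarray           # (n_regions, N+1) coefficients of h1_n
    truncation: int

    def scattering_cross_section(self) -> float:
        """Total scattered power / incident intensity (m^2), real exterior k."""
        k = self.wavenumbers[0]
        n = np.arange(self.truncation + 1)
        s = self.outgoing[0]
        return float(4.0 * np.pi / np.real(k) ** 2 * np.sum((2 * n + 1) * np.abs(s) ** 2))

    def extinction_cross_section(self) -> float:
        """Extinction via the optical theorem (forward-scattering amplitude)."""
        k = self.wavenumbers[0]
        n = np.arange(self.truncation + 1)
        s = self.outgoing[0]
        return float(-4.0 * np.pi / np.real(k) ** 2 * np.sum((2 * n + 1) * np.real(s)))

    def interface_residuals(self) -> tuple[float, float]:
        """Max relative jumps of p and (1/rho) dp/dr across all interfaces."""
        m = self.model
        res_p, res_v = 0.0, 0.0
        for i, r in enumerate(m.radii):
            ko, ki = self.wavenumbers[i], self.wavenumbers[i + 1]
            ro, ri = m.media[i].rho, m.media[i + 1].rho
            vals = []
            for reg, k, rho in (((i, ko, ro)), ((i + 1, ki, ri))):
                n = np.arange(self.truncation + 1)
                j = spherical_jn(n, k * r)
                h = _sph_h1(n, np.full(n.shape, k * r, dtype=complex))
                jp = spherical_jn(n, k * r, derivative=True)
                hp = _sph_h1(n, np.full(n.shape, k * r, dtype=complex), derivative=True)
                p = self.regular[reg] * j + self.outgoing[reg] * h
                v = (k / rho) * (self.regular[reg] * jp + self.outgoing[reg] * hp)
                vals.append((p, v))
            (p_o, v_o), (p_i, v_i) = vals
            scale_p = np.max(np.abs(p_o)) + np.max(np.abs(p_i)) + 1e-300
            scale_v = np.max(np.abs(v_o)) + np.max(np.abs(v_i)) + 1e-300
            res_p = max(res_p, float(np.max(np.abs(p_o - p_i)) / scale_p))
            res_v = max(res_v, float(np.max(np.abs(v_o - v_i)) / scale_v))
        return res_p, res_v


def truncation_order(model: LayeredSphereModel, f: float, margin: int = 12) -> int:
    """Series truncation ``ceil(max_m Re(k_m) * a_outer) + margin``."""
    ka = max(
        np.real(complex_wavenumber(med, f)) * model.radii[0] for med in model.media
    )
    return int(np.ceil(ka)) + margin


def solve_modal(model: LayeredSphereModel, f: float,
                truncation: int | None = None) -> ModalSolution:
    """Solve the per-order interface-continuity systems at frequency ``f``.

    Each modal order n yields a (2L x 2L) linear system (L = number of
    interfaces) for the outgoing exterior coefficient, the layer
    coefficient pairs and the regular core coefficient.  Columns are
    equilibrated before solving because j_n and h_n differ by many orders
    of magnitude once n exceeds |k| r.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    N = truncation_order(model, f) if truncation is None else int(truncation)
    L = len(model.radii)
    nreg = model.n_regions
    k = np.array([complex_wavenumber(med, f) for med in model.media])
    rho = np.array([med.rho for med in model.media], dtype=float)

    regular = np.zeros((nreg, N + 1), dtype=complex)
    outgoing = np.zeros((nreg, N + 1), dtype=complex)
    regular[0, :] = 1.0  # incident plane wave, unit amplitude

    # unknown layout: [B_0, A_1, B_1, ..., A_{L-1}, B_{L-1}, A_L]
    def col_of(region: int, kind: str) -> int:
        if region == 0:
            return 0
        if region == L:
            return 2 * L - 1
        return 1 + 2 * (region - 1) + (0 if kind == "j" else 1)

    for n in range(N + 1):
        A = np.zeros((2 * L, 2 * L), dtype=complex)
        b = np.zeros(2 * L, dtype=complex)
        for i, r in enumerate(model.radii):
            out_reg, in_reg = i, i + 1
            rows = (2 * i, 2 * i + 1)
            for reg, sign in ((out_reg, 1.0), (in_reg, -1.0)):
                z = k[reg] * r
                j = spherical_jn(n, z)
                jp = spherical_jn(n, z, derivative=True)
                h = _sph_h1(n, np.asarray(z, dtype=complex))
                hp = _sph_h1(n, np.asarray(z, dtype=complex), derivative=True)
                vj = k[reg] / rho[reg] * jp
                vh = k[reg] / rho[reg] * hp
                if reg == 0:
                    A[rows[0], col_of(0, "h")] += sign * h
                    A[rows[1], col_of(0, "h")] += sign * vh
                    b[rows[0]] -= sign * j   # known incident part
                    b[rows[1]] -= sign * vj
                elif reg == L:
                    A[rows[0], col_of(L, "j")] += sign * j
                    A[rows[1], col_of(L, "j")] += sign * vj
                else:
                    A[rows[0], col_of(reg, "j")] += sign * j
                    A[rows[1], col_of(reg, "j")] += sign * vj
                    A[rows[0], col_of(reg, "h")] += sign * h
                    A[rows[1], col_of(reg, "h")] += sign * vh
        scale = np.max(np.abs(A), axis=0)
        scale[scale == 0] = 1.0
        try:
            x = np.linalg.solve(A / scale, b) / scale
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"singular modal system at order n={n}, f={f} Hz"
            ) from exc
        outgoing[0, n] = x[col_of(0, "h")]
        regular[L, n] = x[col_of(L, "j")]
        for m in range(1, L):
            regular[m, n] = x[col_of(m, "j")]
            outgoing[m, n] = x[col_of(m, "h")]

    sol = ModalSolution(model=model, f=float(f), wavenumbers=k,
                        regular=regular, outgoing=outgoing, truncation=N)
    return sol


def pressure_field(solution: ModalSolution, points: np.ndarray) -> np.ndarray:
    """Complex pressure (Pa) at Cartesian points (n, 3).

    Points exactly on an interface are evaluated from the inner side.  The
    Legendre polynomials are generated by upward recurrence; radial
    functions come from scipy's spherical Bessel routines (complex
    arguments supported).
    """
    m = solution.model
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    d = np.asarray(m.direction)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(r > 0, pts @ d / np.where(r > 0, r, 1.0), 1.0)
    mu = np.clip(mu, -1.0, 1.0)
    region = m.region_of(r)

    N = solution.truncation
    out = np.zeros(pts.shape[0], dtype=complex)
    p_prev = np.ones_like(mu)          # P_0
    p_curr = mu.copy()                 # P_1
    for n in range(N + 1):
        if n == 0:
            pn = p_prev
        elif n == 1:
            pn = p_curr
        else:
            pn = ((2 * n - 1) * mu * p_curr - (n - 1) * p_prev) / n
            p_prev, p_curr = p_curr, pn
        radial = np.zeros(pts.shape[0], dtype=complex)
        for reg in range(m.n_regions):
            mask = region == reg
            if not np.any(mask):
                continue
            z = solution.wavenumbers[reg] * r[mask]
            zc = np.asarray(z, dtype=complex)
            term = solution.regular[reg, n] * spherical_jn(n, zc)
            if solution.outgoing[reg, n] != 0.0:
                term = term + solution.outgoing[reg, n] * _sph_h1(n, zc)
            radial[mask] = term
        out += (1j ** n) * (2 * n + 1) * pn * radial
    return m.amplitude * out


def sweep_inner_sphere(
    model: LayeredSphereModel,
    frequencies: np.ndarray,
    grid_points: np.ndarray,
    centre: np.ndarray | None = None,
):
    """Frequency sweep of inner-sphere exposure metrics.

    Solves the modal problem at each frequency (the model's wavenumbers are
    re-evaluated per band) and reports the impact SPL and l-infinity SPL
    over ``grid_points`` — which must lie strictly inside the innermost
    radius — plus the complex pressure at ``centre`` (default: origin).
    """
    from uteroacoustics.metrics import SweepResult, impact_spl, linf_spl

    pts = np.atleast_2d(np.asarray(grid_points, dtype=float))
    if np.any(np.linalg.norm(pts, axis=1) >= model.radii[-1]):
        raise ValueError("grid points must lie strictly inside the innermost sphere")
    if centre is None:
        centre = np.zeros(3)
    freqs = np.asarray(frequencies, dtype=float)
    rms = np.empty(freqs.size)
    linf = np.empty(freqs.size)
    pc = np.empty(freqs.size, dtype=complex)
    for i, f in enumerate(freqs):
        sol = solve_modal(model, float(f))
        p = pressure_field(sol, pts)
        rms[i] = impact_spl(p)
        linf[i] = linf_spl(p)
        pc[i] = pressure_field(sol, centre[None, :])[0]
    return SweepResult(
        frequencies=freqs, spl_rms=rms, spl_linf=linf, barycentre_pressure=pc,
        region="uterus",
        metadata={
            "solver": "analytic layered sphere",
            "radii_m": list(model.radii),
            "media": [med.name for med in model.media],
        },
    )
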