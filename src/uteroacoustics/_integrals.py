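"""Quadrature rules and closed-form static potentials for flat triangles.

Building blocks of the Galerkin boundary-element assembly:

* symmetric Gauss rules on the reference triangle (barycentric points and
  weights normalised so that ``integral = area * sum(w_i * f_i)``);
* exact integrals of the Laplace kernel ``1/(4 pi r)`` and its normal
  derivative, with constant and linear densities, over a flat triangle at an
  arbitrary observation point.  These regularise the singular and
  near-singular element pairs: the oscillatory remainder
  ``(exp(ikr) - 1) / (4 pi r)`` is bounded and handled by ordinary
  quadrature, while the ``1/r`` parts are integrated analytically
  (line-integral reductions of the classic potential-of-a-triangle
  formulas).
"""

from __future__ import annotations

import numpy as np

__all__ = ["triangle_rule", "static_triangle_potentials", "p1_gradients"]

_EPS = 1e-14

# barycentric symmetric Gauss rules; (weights, barycentric coords)
_RULES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _perm3(w, a, b, c):
    pts = {(a, b, c), (a, c, b), (b, a, c), (b, c, a), (c, a, b), (c, b, a)}
    return [(w, p) for p in sorted(pts)]


def _build_rules() -> None:
    rules = {}
    rules[1] = [(1.0, (1 / 3, 1 / 3, 1 / 3))]
    rules[3] = _perm3(1 / 3, 2 / 3, 1 / 6, 1 / 6)
    rules[4] = [(-27 / 48, (1 / 3, 1 / 3, 1 / 3))] + _perm3(25 / 48, 0.6, 0.2, 0.2)
    rules[6] = (
        _perm3(0.223381589678011, 0.108103018168070, 0.445948490915965, 0.445948490915965)
        + _perm3(0.109951743655322, 0.816847572980459, 0.091576213509771, 0.091576213509771)
    )
    rules[7] = (
        [(0.225, (1 / 3, 1 / 3, 1 / 3))]
        + _perm3(0.132394152788506, 0.059715871789770, 0.470142064105115, 0.470142064105115)
        + _perm3(0.125939180544827, 0.797426985353087, 0.101286507323456, 0.101286507323456)
    )
    rules[12] = (
        _perm3(0.116786275726379, 0.501426509658179, 0.249286745170910, 0.249286745170910)
        + _perm3(0.050844906370207, 0.873821971016996, 0.063089014491502, 0.063089014491502)
        + _perm3(0.082851075618374, 0.053145049844817, 0.310352451033784, 0.636502499121399)
    )
    for n, rows in rules.items():
        w = np.array([r[0] for r in rows])
        b = np.array([r[1] for r in rows])
        _RULES[n] = (w, b)


_build_rules()


def triangle_rule(npoints: int) -> tuple[np.ndarray, np.ndarray]:
    """Weights (n,) and barycentric coordinates (n, 3); weights sum to 1."""
    if npoints not in _RULES:
        raise ValueError(f"no {npoints}-point rule; available: {sorted(_RULES)}")
    w, b = _RULES[npoints]
    return w.copy(), b.copy()


def p1_gradients(corners: np.ndarray) -> np.ndarray:
    """In-plane gradients of the three P1 (barycentric) basis functions.

    ``corners`` is (..., 3, 3); returns (..., 3, 3) with ``out[..., a, :]``
    the constant surface gradient of the hat function of vertex ``a``.
    """
    v0, v1, v2 = corners[..., 0, :], corners[..., 1, :], corners[..., 2, :]
    cr = np.cross(v1 - v0, v2 - v0)
    nrm2 = np.einsum("...i,...i->...", cr, cr)[..., None]
    # grad(lambda_a) = n x e_a / |n|^2 * |n| ... derive via n x (opposite edge)
    g0 = np.cross(cr, v2 - v1) / nrm2
    g1 = np.cross(cr, v0 - v2) / nrm2
    g2 = np.cross(cr, v1 - v0) / nrm2
    return np.stack([g0, g1, g2], axis=-2)


def static_triangle_potentials(x: np.ndarray, corners: np.ndarray):
    """Closed-form Laplace-kernel integrals over flat triangles.

    Parameters
    ----------
    x:
        Observation points, (n, 3).
    corners:
        Triangle corners paired with the points, (n, 3, 3).

    Returns
    -------
    SL:
        (n, 3): ``integral lambda_b(y) / (4 pi |x-y|) dS_y`` per P1 basis b.
    DL:
        (n, 3): ``integral lambda_b(y) (x-y).n_y / (4 pi |x-y|^3) dS_y``.
    SL1:
        (n,): same single-layer integral with unit density.

    All quantities remain finite for ``x`` on the triangle (the double layer
    tends to zero there since ``(x-y).n = 0``).
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(corners, dtype=float)
    v = [c[:, 0], c[:, 1], c[:, 2]]
    cr = np.cross(v[1] - v[0], v[2] - v[0])
    two_area = np.linalg.norm(cr, axis=1)
    nhat = cr / two_area[:, None]
    w = np.einsum("ni,ni->n", x - v[0], nhat)            # signed height
    rho0 = x - w[:, None] * nhat                          # in-plane projection

    I0 = np.zeros(len(x))
    beta_sum = np.zeros(len(x))
    I1 = np.zeros((len(x), 3))
    J1 = np.zeros((len(x), 3))
    for a in range(3):
        p, q = v[a], v[(a + 1) % 3]
        edge = q - p
        le = np.linalg.norm(edge, axis=1)
        u = edge / le[:, None]
        m = np.cross(u, nhat)                             # outward in-plane normal
        t = np.einsum("ni,ni->n", p - rho0, m)            # distance to edge line
        lm = np.einsum("ni,ni->n", p - rho0, u)
        lp = np.einsum("ni,ni->n", q - rho0, u)
        Rm = np.linalg.norm(x - p, axis=1)
        Rp = np.linalg.norm(x - q, axis=1)
        R02 = t * t + w * w

        # stable log of ((Rp + lp)/(Rm + lm)); both re-expressions agree,
        # pick the numerically safe one depending on the sign of (lp + lm)
        pos = lp + lm >= 0
        num = np.where(pos, Rp + lp, Rm - lm)
        den = np.where(pos, Rm + lm, Rp - lp)
        f2 = np.log(np.maximum(num, _EPS) / np.maximum(den, _EPS))

        absw = np.abs(w)
        beta = np.arctan2(t * lp, R02 + absw * Rp) - np.arctan2(t * lm, R02 + absw * Rm)

        I0 += t * f2 - absw * beta
        beta_sum += beta
        I1 += m * (0.5 * (R02 * f2 + lp * Rp - lm * Rm))[:, None]
        J1 -= m * f2[:, None]

    # signed solid angle:  w * integral(1/r^3) = sign(w) * sum(beta);
    # for x in the triangle plane take the principal value (zero)
    wtol = 1e-10 * np.sqrt(two_area)
    omega_signed = np.where(np.abs(w) > wtol, np.sign(w) * beta_sum, 0.0)

    # linear basis: lambda_b(y) = lambda_b(rho0) + grad_b . (rho(y) - rho0)
    grads = p1_gradients(c)                               # (n, 3, 3)
    lam0 = _barycentric_affine(rho0, v)                   # (n, 3)

    SL = (lam0 * I0[:, None] + np.einsum("nbi,ni->nb", grads, I1)) / (4 * np.pi)
    DL = (lam0 * omega_signed[:, None]
          + w[:, None] * np.einsum("nbi,ni->nb", grads, J1)) / (4 * np.pi)
    return SL, DL, I0 / (4 * np.pi)


def _barycentric_affine(p: np.ndarray, v: list) -> np.ndarray:
    """Affine barycentric coordinates of in-plane points (may lie outside)."""
    e1 = v[1] - v[0]
    e2 = v[2] - v[0]
    d = p - v[0]
    a11 = np.einsum("ni,ni->n", e1, e1)
    a12 = np.einsum("ni,ni->n", e1, e2)
    a22 = np.einsum("ni,ni->n", e2, e2)
    b1 = np.einsum("ni,ni->n", d, e1)
    b2 = np.einsum("ni,ni->n", d, e2)
    det = a11 * a22 - a12 * a12
    l1 = (a22 * b1 - a12 * b2) / det
    l2 = (a11 * b2 - a12 * b1) / det
    return np.stack([1.0 - l1 - l2, l1, l2], axis=1)
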