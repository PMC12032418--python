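"""Boundary-element solver: operator identities, transparency, oracles."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from uteroacoustics.bem import (
    PlaneWave,
    QuadratureConfig,
    TransmissionProblem,
    _assemble_blocks,
    _potential_matrices,
    _Space,
    assemble,
    evaluate_field,
    solve,
    wavelength_audit,
)
from uteroacoustics.layered_sphere import LayeredSphereModel, pressure_field, solve_modal
from uteroacoustics.media import AIR, Medium, get_medium
from uteroacoustics.metrics import impact_spl
from uteroacoustics.phantom import (
    NestedTopology,
    icosphere,
    interior_grid,
    nested_sphere_phantom,
    nested_three_region_phantom,
)

QUAD = QuadratureConfig()
SAME = Medium("same", 343.0, 1.2)


def _unit_sphere_traces(mesh, k, direction=(0.0, 0.0, 1.0)):
    pw = PlaneWave(direction)
    vn = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    gD = pw.pressure(k, mesh.vertices)
    gN = pw.normal_derivative(k, mesh.vertices, vn)
    return gD, gN


class TestOperatorIdentities:
    """Calderon trace identities for an entire plane wave on a sphere:
    V g_N - K g_D = g_D / 2 and K' g_N + W g_D = g_N / 2 (Galerkin-tested).
    The residual is dominated by the faceting of the sphere and must shrink
    at ~O(h^2) under refinement."""

    def test_identities_and_convergence(self):
        errs = {"D": [], "N": []}
        k = 2.0
        for sub in (1, 2):
            mesh = icosphere(1.0, sub)
            spc = _Space(mesh, QUAD)
            V, K, W = _assemble_blocks(spc, spc, k, QUAD)
            gD, gN = _unit_sphere_traces(mesh, k)
            M = spc.mass
            errs["D"].append(
                np.linalg.norm(V @ gN - K @ gD - 0.5 * M @ gD)
                / np.linalg.norm(0.5 * M @ gD))
            errs["N"].append(
                np.linalg.norm(K.T @ gN + W @ gD - 0.5 * M @ gN)
                / np.linalg.norm(0.5 * M @ gN))
        for key in errs:
            assert errs[key][1] < 0.06
            assert errs[key][1] < 0.4 * errs[key][0]  # ~4x per refinement

    def test_point_source_representation(self, rng):
        """Exterior representation of a radiating point source reproduces it.

        u = G(., x0) with x0 inside the sphere is a radiating exterior
        solution; DL[u] - SL[du/dn] must equal u outside.
        """
        k = 3.0
        x0 = np.array([0.2, -0.1, 0.3])

        def g(x):
            r = np.linalg.norm(x - x0, axis=1)
            return np.exp(1j * k * r) / (4 * np.pi * r)

        def dgdn(x, n):
            d = x - x0
            r = np.linalg.norm(d, axis=1)
            return (np.einsum("pi,pi->p", d, n) / r
                    * (1j * k - 1.0 / r) * np.exp(1j * k * r) / (4 * np.pi * r))

        pts = rng.normal(size=(25, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * \
            rng.uniform(1.4, 3.0, 25)[:, None]
        errs = []
        for sub in (3, 4):
            mesh = icosphere(1.0, sub)
            spc = _Space(mesh, QUAD)
            verts = mesh.vertices
            vn = verts / np.linalg.norm(verts, axis=1, keepdims=True)
            SL, DL = _potential_matrices(spc, k, pts, QUAD)
            u_rep = DL @ g(verts) - SL @ dgdn(verts, vn)
            errs.append(np.max(np.abs(u_rep - g(pts))) / np.max(np.abs(g(pts))))
        assert errs[1] < 0.01           # < 1% at the finer mesh
        assert errs[1] < 0.4 * errs[0]  # ~O(h^2) decay of the residual


@pytest.fixture(scope="module")
def zero_contrast_solution():
    mesh = icosphere(0.25, 2, region_label="core")
    topo = NestedTopology([mesh], [-1], {"exterior": SAME, "core": SAME})
    prob = TransmissionProblem(topo, 500.0, PlaneWave((1.0, 0.0, 0.0)))
    system = assemble(prob, QUAD, audit="skip")
    return prob, system, solve(system)


class TestZeroContrast:
    def test_traces_reproduce_incident(self, zero_contrast_solution):
        prob, system, sol = zero_contrast_solution
        spc = system.spaces[0]
        k0 = prob.region_wavenumber(0)
        # against the L2 projection of the exact incident trace
        proj = spla.spsolve(spc.mass.astype(complex).tocsc(),
                            system.rhs[:spc.nverts])
        err = np.linalg.norm(sol.dirichlet[0] - proj) / np.linalg.norm(proj)
        assert err < 1e-2
        gD = prob.incident.pressure(k0, spc.mesh.vertices)
        assert np.linalg.norm(sol.dirichlet[0] - gD) / np.linalg.norm(gD) < 0.05

    def test_field_is_incident_everywhere(self, zero_contrast_solution):
        prob, _, sol = zero_contrast_solution
        interior = np.array([[0.05, 0.02, -0.01], [0.1, 0.0, 0.05],
                             [0.0, -0.1, 0.0]])
        exterior = np.array([[0.35, 0.1, 0.0], [0.0, -0.5, 0.2]])
        k0 = prob.region_wavenumber(0)
        err_in = np.abs(evaluate_field(sol, interior).pressure
                        - prob.incident.pressure(k0, interior))
        assert np.max(err_in) < 0.01
        # exterior: nodal incident-trace subtraction adds O(h^2) interpolation
        # error on the faceted sphere, so the contract is looser there
        err_ex = np.abs(evaluate_field(sol, exterior).pressure
                        - prob.incident.pressure(k0, exterior))
        assert np.max(err_ex) < 0.03

    def test_gmres_matches_direct_solve(self, zero_contrast_solution):
        _, system, sol = zero_contrast_solution
        direct = solve(system, method="direct")
        x_g = np.concatenate(sol.dirichlet + sol.neumann_scaled)
        x_d = np.concatenate(direct.dirichlet + direct.neumann_scaled)
        assert np.linalg.norm(x_g - x_d) / np.linalg.norm(x_d) < 1e-4
        assert sol.residual <= 1e-4
        assert sol.iterations <= 2000

    def test_assembly_determinism(self):
        mesh = icosphere(0.2, 1, region_label="core")
        topo = NestedTopology([mesh], [-1], {"exterior": SAME, "core": SAME})
        prob = TransmissionProblem(topo, 300.0, PlaneWave((1.0, 0.0, 0.0)))
        a = assemble(prob, QUAD, audit="skip")
        b = assemble(prob, QUAD, audit="skip")
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.rhs, b.rhs)
        sa, sb = solve(a), solve(b)
        assert np.array_equal(sa.dirichlet[0], sb.dirichlet[0])


@pytest.fixture(scope="module")
def setup():
    """Air outside, tissue sphere: BEM solution and the analytical series."""
    f = 500.0
    tissue = get_medium("Abdominal tissue")
    mesh = icosphere(0.25, 2, region_label="core")
    topo = NestedTopology([mesh], [-1], {"exterior": AIR, "core": tissue})
    prob = TransmissionProblem(topo, f, PlaneWave((1.0, 0.0, 0.0)))
    sol = solve(assemble(prob, QUAD, audit="skip"))
    model = LayeredSphereModel(radii=(0.25,), media=(AIR, tissue))
    return prob, sol, solve_modal(model, f)


class TestSingleSphereOracle:
    """BEM against the analytical series on a single penetrable sphere."""

    def test_interior_field_and_rms(self, setup, rng):
        prob, sol, ana = setup
        pts = rng.normal(size=(150, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * \
            rng.uniform(0.0, 0.17, 150)[:, None]
        pb = evaluate_field(sol, pts).pressure
        pa = pressure_field(ana, pts)
        assert np.max(np.abs(pb - pa)) / np.max(np.abs(pa)) < 0.02
        assert abs(impact_spl(pb) - impact_spl(pa)) < 0.5

    def test_extinction_interior_null_field(self, setup):
        """Exterior representation inside the scatterer extinguishes the
        incident wave: DL[p] - SL[dp/dn] = -p_inc there."""
        prob, sol, _ = setup
        spc = sol.spaces[0]
        k0 = prob.region_wavenumber(0)
        pts = np.array([[0.0, 0.0, 0.0], [0.1, 0.05, -0.03], [-0.1, 0.0, 0.08]])
        SL, DL = _potential_matrices(spc, k0, pts, QUAD)
        rho0 = prob.region_medium(0).rho
        val = DL @ sol.dirichlet[0] - SL @ (rho0 * sol.neumann_scaled[0])
        pinc = prob.incident.pressure(k0, pts)
        np.testing.assert_allclose(val, -pinc, atol=0.02)

    def test_reciprocity_direction_swap(self, setup, rng):
        """+x and -x incidence give mirror-image interior fields."""
        prob, sol, _ = setup
        prob2 = TransmissionProblem(prob.topology, prob.frequency,
                                    PlaneWave((-1.0, 0.0, 0.0)))
        sol2 = solve(assemble(prob2, QUAD, audit="skip"))
        pts = rng.normal(size=(40, 3)) * 0.05
        p1 = evaluate_field(sol, pts).pressure
        p2 = evaluate_field(sol2, -pts).pressure
        np.testing.assert_allclose(np.abs(p1), np.abs(p2), rtol=5e-3, atol=1e-4)


class TestNestedAndSiblings:
    def test_three_region_zero_contrast(self):
        """Generic multi-domain assembly: abdomen + uterus + sibling spine,
        all media identical, must be acoustically transparent."""
        media = {"exterior": SAME, "abdomen": SAME, "uterus": SAME, "spine": SAME}
        topo = nested_three_region_phantom(
            0.25, 0.12, (0.03, 0.03, 0.15), (-0.18, 0.0, 0.0), 5.0, 300.0,
            media=media)
        prob = TransmissionProblem(topo, 300.0, PlaneWave((0.0, 0.0, 1.0)))
        sol = solve(assemble(prob, QUAD, audit="skip"))
        pts = np.array([[0.0, 0.0, 0.0], [-0.18, 0.0, 0.05],
                        [0.3, 0.0, 0.0], [0.05, 0.05, -0.02]])
        fv = evaluate_field(sol, pts)
        pinc = prob.incident.pressure(prob.region_wavenumber(0), pts)
        keep = ~fv.near_surface
        assert np.all(keep[:2])
        assert np.max(np.abs(fv.pressure[keep] - pinc[keep])) < 0.01

    def test_two_sphere_vs_analytic_low_band(self):
        """Fig-of-merit check at 500 Hz: transmission through the shell
        agrees with the layered-sphere series within 0.5 dB."""
        f = 500.0
        topo = nested_sphere_phantom(0.25, 0.15, 5.0, f)
        prob = TransmissionProblem(topo, f, PlaneWave((1.0, 0.0, 0.0)))
        sol = solve(assemble(prob, QUAD))
        eg = interior_grid(icosphere(0.15, 3), spacing=0.3 / 15)
        fv = evaluate_field(sol, eg.points)
        keep = ~fv.near_surface
        model = LayeredSphereModel(
            radii=(0.25, 0.15),
            media=(AIR, get_medium("Abdominal tissue"), get_medium("Amniotic fluid")))
        pa = pressure_field(solve_modal(model, f), eg.points)
        assert abs(impact_spl(fv.pressure[keep]) - impact_spl(pa[keep])) < 0.5


class TestAuditsAndFlags:
    def test_wavelength_audit_records(self):
        topo = nested_sphere_phantom(0.25, 0.15, 5.0, 1000.0)
        recs = wavelength_audit(topo, 1000.0)
        assert all(r["ok"] for r in recs)
        # same mesh audited at a much higher frequency fails
        recs_hi = wavelength_audit(topo, 16000.0)
        assert not all(r["ok"] for r in recs_hi)

    def test_assemble_audit_modes(self):
        topo = nested_sphere_phantom(0.25, 0.15, 5.0, 200.0)
        prob = TransmissionProblem(topo, 6000.0, PlaneWave((1.0, 0.0, 0.0)))
        with pytest.raises(ValueError):
            assemble(prob, QUAD, audit="error")
        with pytest.warns(UserWarning):
            assemble(prob, QUAD, audit="warn")

    def test_near_surface_points_flagged(self, zero_contrast_solution):
        _, _, sol = zero_contrast_solution
        fv = evaluate_field(sol, np.array([[0.0, 0.0, 0.2495], [0.0, 0.0, 0.0]]))
        assert bool(fv.near_surface[0]) is True
        assert bool(fv.near_surface[1]) is False
        assert fv.valid().shape == (1,)
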