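"""Unit tests of the plane-stress voxel FE core."""

import numpy as np
import pytest

from bonesim.fe_core import (
    DensityField,
    LoadSpec,
    MaterialLaw,
    MeshSpec,
    boundary_tractions,
    build_mesh,
    element_stiffness_unit,
    solve_static,
    stress_tensor,
    tractions_from_stress,
    young_modulus,
)

from conftest import random_density


class TestYoungModulus:
    @pytest.mark.parametrize(
        "m, expected",
        [(1.0, 500.0), (0.7, 171.5), (0.01, 5e-4)],
    )
    def test_power_law_values(self, m, expected):
        assert young_modulus(m) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        m = np.linspace(0.01, 1.0, 200)
        e = young_modulus(m)
        assert np.all(np.diff(e) > 0)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_out_of_range_named_in_error(self, bad):
        with pytest.raises(ValueError, match=str(bad)):
            young_modulus(bad)


class TestMesh:
    def test_default_counts_and_area(self, default_mesh):
        assert default_mesh.n_remodelable == 6400
        assert default_mesh.spec.element_area_mm2 == pytest.approx(6.25e-4)
        t = default_mesh.spec.side_plate_thickness
        assert default_mesh.n_elements == (80 + 2 * t) ** 2

    def test_no_frame_all_remodelable(self):
        mesh = build_mesh(MeshSpec(nx=4, ny=4, side_plate_thickness=0))
        assert mesh.n_elements == 16
        assert mesh.remodelable.all()

    def test_side_plates_form_frame(self, default_mesh):
        mask = default_mesh.remodelable
        assert not mask[0].any() and not mask[-1].any()
        assert not mask[:, 0].any() and not mask[:, -1].any()
        assert mask[2:-2, 2:-2].all()

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            MeshSpec(nx=2)
        with pytest.raises(ValueError):
            MeshSpec(width_mm=-1)


class TestTractions:
    def test_phi_zero_is_unrotated_principal_frame(self):
        sxx, syy, sxy = stress_tensor(LoadSpec(magnitude=2.0, orientation_phi=0.0))
        assert (sxx, syy, sxy) == pytest.approx((2.0, -2.0, 0.0), abs=1e-12)

    def test_phi_30_components(self):
        sxx, syy, sxy = stress_tensor(LoadSpec(magnitude=2.0, orientation_phi=30.0))
        assert sxx == pytest.approx(1.0)
        assert syy == pytest.approx(-1.0)
        assert sxy == pytest.approx(np.sqrt(3.0))

    def test_rotating_by_90_swaps_principal_axes(self):
        a = stress_tensor(LoadSpec(orientation_phi=10.0))
        b = stress_tensor(LoadSpec(orientation_phi=100.0))
        assert b[0] == pytest.approx(-a[0]) and b[1] == pytest.approx(-a[1])

    def test_zero_load_factor_gives_zero_forces(self, small_mesh):
        f = boundary_tractions(small_mesh, LoadSpec(load_factor=0.0))
        assert np.all(f == 0.0)

    def test_forces_self_equilibrated(self, small_mesh):
        f = boundary_tractions(small_mesh, LoadSpec())
        assert f.reshape(-1, 2).sum(axis=0) == pytest.approx(np.zeros(2), abs=1e-12)


class TestSolveStatic:
    def test_homogeneous_uniaxial_closed_form(self):
        mesh = build_mesh(MeshSpec(nx=8, ny=8, width_mm=0.2, height_mm=0.2,
                                   side_plate_thickness=0))
        mat = MaterialLaw(poisson_ratio=0.0)
        sigma = 2.0
        fe = solve_static(
            mesh,
            DensityField.uniform(mesh, 1.0),
            material=mat,
            forces=tractions_from_stress(mesh, sigma, 0.0, 0.0),
        )
        assert fe.strain[..., 0] == pytest.approx(sigma / 500.0, rel=1e-9)
        assert fe.sed == pytest.approx(0.5 * sigma**2 / 500.0, rel=1e-9)

    def test_linearity_and_quadratic_sed(self, small_mesh, rng):
        density = random_density(small_mesh, rng)
        fe1 = solve_static(small_mesh, density, LoadSpec(load_factor=1.0))
        fe08 = solve_static(small_mesh, density, LoadSpec(load_factor=0.8))
        assert fe08.strain == pytest.approx(0.8 * fe1.strain, rel=1e-8)
        assert fe08.sed == pytest.approx(0.64 * fe1.sed, rel=1e-8)

    def test_sed_nonnegative_for_random_fields(self, small_mesh, rng):
        for _ in range(3):
            fe = solve_static(small_mesh, random_density(small_mesh, rng), LoadSpec())
            assert (fe.sed >= 0.0).all()

    def test_patch_test_constant_strain(self):
        # prescribed linear displacement field on every boundary node must be
        # reproduced with a constant strain state to machine precision
        mesh = build_mesh(MeshSpec(nx=4, ny=4, side_plate_thickness=0,
                                   width_mm=0.1, height_mm=0.1))
        exx, eyy, gxy = 1e-3, -4e-4, 5e-4
        coords = mesh.node_coords()
        n_side = mesh.nx_total + 1
        boundary = set()
        for nid, (x, y) in enumerate(coords):
            r, c = divmod(nid, n_side)
            if r in (0, mesh.ny_total) or c in (0, mesh.nx_total):
                boundary.add(nid)
        bc = {}
        for nid in boundary:
            x, y = coords[nid]
            bc[2 * nid] = exx * x + 0.5 * gxy * y
            bc[2 * nid + 1] = eyy * y + 0.5 * gxy * x
        fe = solve_static(
            mesh,
            DensityField.uniform(mesh, 1.0),
            forces=np.zeros(mesh.n_dofs),
            dirichlet=bc,
        )
        assert fe.strain[..., 0] == pytest.approx(exx, rel=1e-10)
        assert fe.strain[..., 1] == pytest.approx(eyy, rel=1e-10)
        assert fe.strain[..., 2] == pytest.approx(gxy, rel=1e-10)

    def test_stiffer_never_stores_more_energy(self, small_mesh, rng):
        # under fixed tractions, raising every density lowers compliance
        d1 = random_density(small_mesh, rng, lo=0.1, hi=0.6)
        d2 = DensityField(np.clip(d1.m + 0.3, None, 1.0))
        area = small_mesh.spec.element_area_mm2 * small_mesh.spec.thickness_mm
        e1 = solve_static(small_mesh, d1, LoadSpec()).sed.sum() * area
        e2 = solve_static(small_mesh, d2, LoadSpec()).sed.sum() * area
        assert e2 <= e1

    def test_density_shape_mismatch(self, small_mesh):
        with pytest.raises(ValueError, match="shape"):
            solve_static(small_mesh, np.ones((3, 3)), LoadSpec())


class TestStiffnessOracle:
    def test_element_stiffness_matches_symbolic_integration(self, small_mesh):
        sympy = pytest.importorskip("sympy")
        xi, eta = sympy.symbols("xi eta")
        hx, hy = small_mesh.hx, small_mesh.hy
        nu = sympy.Rational(3, 10)
        N = [
            (1 - xi) * (1 - eta) / 4,
            (1 + xi) * (1 - eta) / 4,
            (1 + xi) * (1 + eta) / 4,
            (1 - xi) * (1 + eta) / 4,
        ]
        dNdx = [sympy.diff(n, xi) * sympy.Rational(2) / hx for n in N]
        dNdy = [sympy.diff(n, eta) * sympy.Rational(2) / hy for n in N]
        B = sympy.zeros(3, 8)
        for i in range(4):
            B[0, 2 * i] = dNdx[i]
            B[1, 2 * i + 1] = dNdy[i]
            B[2, 2 * i] = dNdy[i]
            B[2, 2 * i + 1] = dNdx[i]
        D = (1 / (1 - nu**2)) * sympy.Matrix(
            [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]]
        )
        integrand = B.T * D * B
        det_j = sympy.Rational(1, 4) * hx * hy
        Ke = sympy.integrate(
            sympy.integrate(integrand * det_j, (xi, -1, 1)), (eta, -1, 1)
        )
        Ke = np.array(Ke.evalf(), dtype=float) * small_mesh.spec.thickness_mm
        num = element_stiffness_unit(small_mesh, 0.3)
        assert num == pytest.approx(Ke, rel=1e-12, abs=1e-15)

    def test_solution_matches_independent_dense_assembly(self, small_mesh, rng):
        # independently coded naive assembly + dense solve as the oracle
        mesh = small_mesh
        density = random_density(mesh, rng, lo=0.2)
        mat = MaterialLaw()
        ke = element_stiffness_unit(mesh, mat.poisson_ratio)
        K = np.zeros((mesh.n_dofs, mesh.n_dofs))
        E = young_modulus(density.m, mat).ravel()
        for e in range(mesh.n_elements):
            dofs = mesh.element_dofs[e]
            for i in range(8):
                for j in range(8):
                    K[dofs[i], dofs[j]] += E[e] * ke[i, j]
        f = boundary_tractions(mesh, LoadSpec())
        fixed = [0, 1, 2 * mesh.nx_total + 1]
        free = np.setdiff1d(np.arange(mesh.n_dofs), fixed)
        u = np.zeros(mesh.n_dofs)
        u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
        fe = solve_static(mesh, density, LoadSpec())
        ref = np.abs(u).max()
        assert fe.displacement.ravel() == pytest.approx(u, abs=1e-6 * ref)
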