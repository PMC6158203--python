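"""FE solver verification: meshing, element matrices, patch test, bar
solutions, equilibrium, principal strains, convergence."""

import numpy as np
import pytest
import sympy as sp

from jawstrain import fem
from jawstrain.errors import MeshError, PlacementError, RigidBodyError, ValidationError
from jawstrain.fem import (
    DirichletBC,
    Material,
    MaterialSet,
    MuscleLoad,
    assemble,
    hex_stiffness,
    principal_strains,
    region_mean,
    solve_static,
    voxel_to_hex_mesh,
)
from jawstrain.volume import HYPERTROPHIC, IMMATURE, LabelVolume

MATS = MaterialSet(immature=Material(E=1.0, nu=0.0), hypertrophic=Material(E=1.0, nu=0.0))


def box_volume(nx, ny, nz, label=IMMATURE, h=1.0):
    g = np.full((nx, ny, nz), label, dtype=np.uint8)
    return LabelVolume(g, voxel_size=h)


def bar_system(L, h=1.0, E=1.0, nu=0.0):
    """1x1xL-um bar along x, discretized at voxel size h."""
    n = int(round(L / h)), int(round(1 / h)), int(round(1 / h))
    vol = box_volume(*n, h=h)
    mesh = voxel_to_hex_mesh(vol)
    mats = MaterialSet(immature=Material(E=E, nu=nu), hypertrophic=Material(E=E, nu=nu))
    return assemble(mesh, mats)


def sympy_unit_cube_stiffness():
    """Independent oracle: exact symbolic integration of the trilinear
    hexahedron stiffness on the unit cube at E=1, nu=0."""
    xi, eta, zeta = sp.symbols("xi eta zeta")
    signs = [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ]
    N = [
        sp.Rational(1, 8) * (1 + sx * xi) * (1 + sy * eta) * (1 + sz * zeta)
        for sx, sy, sz in signs
    ]
    # unit cube: x = (xi+1)/2 etc., so d/dx = 2 d/dxi
    dN = [[2 * sp.diff(n, v) for v in (xi, eta, zeta)] for n in N]
    B = sp.zeros(6, 24)
    for a in range(8):
        dx, dy, dz = dN[a]
        c = 3 * a
        B[0, c], B[1, c + 1], B[2, c + 2] = dx, dy, dz
        B[3, c], B[3, c + 1] = dy, dx
        B[4, c + 1], B[4, c + 2] = dz, dy
        B[5, c], B[5, c + 2] = dz, dx
    # E=1, nu=0: lambda=0, mu=1/2 -> D = diag(1,1,1,1/2,1/2,1/2)
    D = sp.diag(1, 1, 1, sp.Rational(1, 2), sp.Rational(1, 2), sp.Rational(1, 2))
    integrand = B.T * D * B * sp.Rational(1, 8)  # detJ = 1/8
    K = sp.integrate(
        sp.integrate(sp.integrate(integrand, (xi, -1, 1)), (eta, -1, 1)),
        (zeta, -1, 1),
    )
    return np.array(K, dtype=float)


class TestMeshing:
    def test_two_cube_counts(self):
        mesh = voxel_to_hex_mesh(box_volume(2, 2, 2))
        assert mesh.n_elems == 8
        assert mesh.n_nodes == 27

    def test_single_voxel_counts(self):
        mesh = voxel_to_hex_mesh(box_volume(1, 1, 1))
        assert mesh.n_elems == 1
        assert mesh.n_nodes == 8

    def test_element_count_equals_cartilage_voxel_count(self, wt_volume):
        from jawstrain.fem import DEFAULT_REGION_MAP

        mesh = voxel_to_hex_mesh(wt_volume)
        expect = int(np.isin(wt_volume.labels, list(DEFAULT_REGION_MAP)).sum())
        assert mesh.n_elems == expect

    def test_empty_volume_raises(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        with pytest.raises(MeshError):
            voxel_to_hex_mesh(LabelVolume(g))


class TestElementStiffness:
    def test_matches_symbolic_integration_oracle(self):
        Ke = hex_stiffness(Material(E=1.0, nu=0.0), h=1.0)
        K_exact = sympy_unit_cube_stiffness()
        np.testing.assert_allclose(Ke, K_exact, atol=1e-13)

    def test_row_sums_vanish_translation_invariance(self):
        Ke = hex_stiffness(Material(E=3.0, nu=0.3), h=1.0)
        # translating all nodes produces no force
        for ax in range(3):
            t = np.zeros(24)
            t[ax::3] = 1.0
            np.testing.assert_allclose(Ke @ t, 0.0, atol=1e-12)

    def test_doubling_modulus_doubles_stiffness(self):
        K1 = hex_stiffness(Material(E=1.0, nu=0.25), h=1.0)
        K2 = hex_stiffness(Material(E=2.0, nu=0.25), h=1.0)
        np.testing.assert_allclose(K2, 2 * K1, rtol=1e-14)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValidationError):
            Material(E=1.0, nu=0.5)


class TestGlobalSystem:
    def test_six_rigid_body_modes_in_null_space(self):
        sys_ = assemble(voxel_to_hex_mesh(box_volume(3, 3, 3)), MATS)
        X = sys_.mesh.nodes
        modes = []
        for ax in range(3):  # translations
            m = np.zeros((len(X), 3))
            m[:, ax] = 1.0
            modes.append(m)
        for ax in range(3):  # infinitesimal rotations u = omega x r
            omega = np.zeros(3)
            omega[ax] = 1.0
            modes.append(np.cross(omega, X - X.mean(0)))
        for m in modes:
            np.testing.assert_allclose(sys_.K @ m.ravel(), 0.0, atol=1e-9)

    def test_patch_test_reproduces_constant_strain(self):
        """Linear boundary displacement -> exact constant interior strain."""
        sys_ = assemble(voxel_to_hex_mesh(box_volume(4, 4, 4)), MATS)
        mesh = sys_.mesh
        A = np.array([[2e-3, 1e-3, 0.0], [0.0, -1e-3, 5e-4], [0.0, 0.0, 3e-3]])
        lo, hi = mesh.nodes.min(0), mesh.nodes.max(0)
        on_surf = np.any((mesh.nodes <= lo + 1e-9) | (mesh.nodes >= hi - 1e-9), axis=1)
        bc = DirichletBC(
            nodes=np.flatnonzero(on_surf),
            axes=(0, 1, 2),
            value=lambda X: X @ A.T,
        )
        field = solve_static(sys_, [bc])
        expect = 0.5 * (A + A.T)
        np.testing.assert_allclose(
            field.strain, np.broadcast_to(expect, field.strain.shape), atol=1e-10
        )

    def test_uniaxial_bar_matches_closed_form(self):
        """Tip displacement FL/EA and strain F/EA within 1% at nu=0."""
        L, E, F = 20.0, 1.0, 0.004
        sys_ = bar_system(L, E=E)
        mesh = sys_.mesh
        clamped = np.flatnonzero(mesh.nodes[:, 0] <= 1e-9)
        tip = np.flatnonzero(mesh.nodes[:, 0] >= L - 1e-9)
        f = np.zeros(3 * mesh.n_nodes)
        f[3 * tip] = F / len(tip)
        field = solve_static(sys_, [DirichletBC(clamped, (0, 1, 2))], nodal_forces=f)
        assert field.u[tip, 0].mean() == pytest.approx(F * L / E, rel=0.01)
        np.testing.assert_allclose(field.strain[:, 0, 0], F / E, rtol=0.01)

    def test_equilibrium_of_reactions(self):
        sys_ = bar_system(10.0, nu=0.3)
        mesh = sys_.mesh
        clamped = np.flatnonzero(mesh.nodes[:, 0] <= 1e-9)
        load = MuscleLoad(
            "pull", insertion=(10.0, 0.0, 1.0), origin=(20.0, 5.0, 3.0), magnitude=0.01
        )
        field = solve_static(sys_, [DirichletBC(clamped, (0, 1, 2))], [load])
        reactions = fem.reaction_sums(sys_, field)
        applied = field.f.reshape(-1, 3).sum(0)
        np.testing.assert_allclose(
            reactions + applied, 0.0, atol=1e-8 * np.linalg.norm(applied)
        )

    def test_zero_loads_zero_response(self):
        sys_ = bar_system(5.0)
        clamped = np.flatnonzero(sys_.mesh.nodes[:, 0] <= 1e-9)
        field = solve_static(sys_, [DirichletBC(clamped, (0, 1, 2))])
        assert np.all(field.u == 0.0)
        assert np.all(field.strain == 0.0)

    def test_load_scaling_is_exact(self):
        sys_ = bar_system(8.0, nu=0.3)
        clamped = np.flatnonzero(sys_.mesh.nodes[:, 0] <= 1e-9)
        bcs = [DirichletBC(clamped, (0, 1, 2))]
        m1 = MuscleLoad("m", (8.0, 0.0, 1.0), (12.0, 3.0, -4.0), 0.01)
        m2 = MuscleLoad("m", (8.0, 0.0, 1.0), (12.0, 3.0, -4.0), 0.02)
        f1 = solve_static(sys_, bcs, [m1])
        f2 = solve_static(sys_, bcs, [m2])
        np.testing.assert_allclose(f2.u, 2 * f1.u, rtol=1e-12, atol=1e-16)
        np.testing.assert_allclose(f2.strain, 2 * f1.strain, rtol=1e-12, atol=1e-18)

    def test_material_scaling_is_exact(self):
        c = 3.7
        loadargs = dict(
            loads=[MuscleLoad("m", (8.0, 0.0, 1.0), (12.0, 3.0, -4.0), 0.01)]
        )
        s1 = bar_system(8.0, E=1.0, nu=0.3)
        s2 = bar_system(8.0, E=c, nu=0.3)
        clamped = np.flatnonzero(s1.mesh.nodes[:, 0] <= 1e-9)
        bcs = [DirichletBC(clamped, (0, 1, 2))]
        f1 = solve_static(s1, bcs, **loadargs)
        f2 = solve_static(s2, bcs, **loadargs)
        # separate factorizations round independently at ~1e-12 relative
        np.testing.assert_allclose(f2.u, f1.u / c, rtol=1e-10, atol=1e-16)

    def test_unconstrained_system_raises_rigid_body_error(self):
        sys_ = bar_system(4.0)
        with pytest.raises(RigidBodyError):
            solve_static(sys_, [])

    def test_partially_constrained_system_raises(self):
        sys_ = bar_system(4.0)
        clamped = np.flatnonzero(sys_.mesh.nodes[:, 0] <= 1e-9)
        load = MuscleLoad("axial", (4.0, 0.0, 1.0), (9.0, 0.0, 1.0), 0.01)
        with pytest.raises(RigidBodyError):
            solve_static(sys_, [DirichletBC(clamped, (1, 2))], [load])  # x free

    def test_load_far_from_mesh_raises_placement_error(self):
        sys_ = bar_system(4.0)
        clamped = np.flatnonzero(sys_.mesh.nodes[:, 0] <= 1e-9)
        stray = MuscleLoad("stray", (50.0, 50.0, 50.0), (60.0, 50.0, 50.0), 1.0)
        with pytest.raises(PlacementError):
            solve_static(sys_, [DirichletBC(clamped, (0, 1, 2))], [stray])

    def test_bar_error_decreases_under_refinement(self):
        """Clamped-end bar at nu=0.3: tip error shrinks monotonically."""
        L, E, F = 8.0, 1.0, 0.004
        errors = []
        for h in (1.0, 0.5, 0.25):
            sys_ = bar_system(L, h=h, E=E, nu=0.3)
            mesh = sys_.mesh
            clamped = np.flatnonzero(mesh.nodes[:, 0] <= 1e-9)
            tip = np.flatnonzero(mesh.nodes[:, 0] >= L - 1e-9)
            # consistent nodal loads for uniform tip traction: each tip-face
            # element spreads its share equally over its four face nodes
            f = np.zeros(3 * mesh.n_nodes)
            elem_max_x = mesh.nodes[mesh.elems, 0].max(axis=1)
            tip_elems = np.flatnonzero(elem_max_x >= L - 1e-9)
            for e in tip_elems:
                face = [n for n in mesh.elems[e] if mesh.nodes[n, 0] >= L - 1e-9]
                f[np.multiply(face, 3)] += F / (len(tip_elems) * 4)
            field = solve_static(sys_, [DirichletBC(clamped, (0, 1, 2))], nodal_forces=f)
            errors.append(abs(field.u[tip, 0].mean() - F * L / E))
        assert errors[0] > errors[1] > errors[2]


class TestPrincipalStrains:
    def test_diagonal_and_pure_shear_closed_forms(self):
        mesh = voxel_to_hex_mesh(box_volume(1, 1, 2))
        eps = np.zeros((2, 3, 3))
        eps[0] = np.diag([0.01, 0.0, 0.0])
        eps[1, 0, 1] = eps[1, 1, 0] = 0.01  # gamma = 0.02
        field = fem.StrainField(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)), strain=eps)
        principal_strains(field)
        assert field.e_max[0] == pytest.approx(0.01)
        assert field.e_min[0] == pytest.approx(0.0)
        assert field.e_max[1] == pytest.approx(0.01)
        assert field.e_min[1] == pytest.approx(-0.01)

    def test_thousand_random_tensors_match_characteristic_polynomial(self):
        rng = np.random.default_rng(42)
        A = rng.normal(size=(1000, 3, 3))
        eps = 0.5 * (A + np.transpose(A, (0, 2, 1)))
        vals = np.linalg.eigvalsh(eps)[:, ::-1]
        for i in range(1000):
            e = eps[i]
            # char poly: -l^3 + I1 l^2 - I2 l + I3 = 0
            i1 = np.trace(e)
            i2 = 0.5 * (i1**2 - np.trace(e @ e))
            i3 = np.linalg.det(e)
            roots = np.sort(np.roots([1.0, -i1, i2, -i3]).real)[::-1]
            np.testing.assert_allclose(vals[i], roots, atol=1e-10)

    def test_trace_identity(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(50, 3, 3))
        eps = 0.5 * (A + np.transpose(A, (0, 2, 1)))
        mesh = voxel_to_hex_mesh(box_volume(1, 1, 1))
        field = fem.StrainField(
            mesh=mesh, u=np.zeros((mesh.n_nodes, 3)), strain=eps[:1]
        )
        principal_strains(field)
        assert field.principal.sum() == pytest.approx(np.trace(eps[0]), abs=1e-9)

    def test_asymmetric_tensor_rejected(self):
        mesh = voxel_to_hex_mesh(box_volume(1, 1, 1))
        bad = np.zeros((1, 3, 3))
        bad[0, 0, 1] = 1e-3
        field = fem.StrainField(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)), strain=bad)
        with pytest.raises(ValidationError):
            principal_strains(field)


class TestRegionMean:
    def _field(self):
        mesh = voxel_to_hex_mesh(box_volume(10, 1, 1))
        eps = np.zeros((10, 3, 3))
        eps[:, 0, 0] = np.linspace(0.01, 0.1, 10)
        f = fem.StrainField(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)), strain=eps)
        return principal_strains(f)

    def test_matches_hand_weighted_sum(self):
        f = self._field()
        mask = np.zeros(10, dtype=bool)
        mask[[1, 4, 7]] = True
        expect = f.e_max[mask].mean()  # uniform voxel volumes
        assert region_mean(f, mask, "E_Max") == pytest.approx(expect, rel=1e-12)

    def test_constant_field_returns_constant(self):
        f = self._field()
        f.principal[:, 0] = 0.02
        assert region_mean(f, np.ones(10, bool), "E_Max") == pytest.approx(0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            region_mean(self._field(), np.zeros(10, bool), "E_Max")
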