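"""FEM core: assembly, follower loads, fluid cavity, forward solver."""

import numpy as np
import pytest

import eyegap.fem as fem
from eyegap.constitutive import MaterialParameters
from eyegap.fem import (Assembler, BoundaryConditions, FluidCavity,
                        PressureLoad, cavity_state, newton_solve)
from conftest import (octant_symmetry_bcs, spherical_shell_octant,
                      unit_cube_mesh)

NEO = MaterialParameters(K=2.0, mu=1.0, k1=0.0, k2=1.0)


def cube_assembler(params=NEO, **kw):
    mesh = unit_cube_mesh()
    return mesh, Assembler(mesh, {"bulk": params}, **kw)


class TestInternalForces:
    def test_zero_displacement(self):
        mesh, asm = cube_assembler()
        f = asm.internal_force(np.zeros(mesh.n_dofs))
        np.testing.assert_allclose(f, 0.0, atol=1e-13)

    def test_rigid_translation(self):
        mesh, asm = cube_assembler()
        u = np.tile([0.3, -0.2, 0.5], mesh.n_nodes)
        np.testing.assert_allclose(asm.internal_force(u), 0.0, atol=1e-12)

    def test_uniaxial_closed_form(self):
        """Prescribed isochoric stretch: the resultant face force equals
        the analytic neo-Hookean traction."""
        lam = 1.3
        mesh, asm = cube_assembler()
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        u = mesh.nodes @ (F - np.eye(3)).T
        f = asm.internal_force(u.ravel()).reshape(-1, 3)
        face = [1, 2, 5, 6]                      # x = max face nodes
        force_x = f[face, 0].sum()
        I1 = lam ** 2 + 2.0 / lam
        sig11 = NEO.mu * (lam ** 2 - I1 / 3.0)   # J = 1, deviatoric
        area = 1.0 / lam                         # current face area
        assert force_x == pytest.approx(sig11 * area, rel=1e-6)

    def test_linearity_in_parameters(self):
        mesh, _ = cube_assembler()
        rng = np.random.default_rng(1)
        u = 0.05 * rng.standard_normal(mesh.n_dofs)
        fib_kw = {}
        vals = {}
        for scale in (1.0, 2.0):
            params = MaterialParameters(K=scale * 2.0, mu=0.0, k1=0.0, k2=1.0)
            asm = Assembler(mesh, {"bulk": params})
            vals[scale] = asm.internal_force(u)
        np.testing.assert_allclose(vals[2.0], 2.0 * vals[1.0], rtol=1e-13)

    def test_inverted_element_reported(self):
        mesh, asm = cube_assembler()
        u = np.zeros((8, 3))
        u[4:, 2] = -1.5                          # collapse through the base
        with pytest.raises(fem.KinematicsError, match="bulk"):
            asm.internal_force(u.ravel())

    def test_objectivity(self):
        """Rotating the reference and the displacements rotates the
        internal forces."""
        from scipy.spatial.transform import Rotation
        mesh = unit_cube_mesh()
        params = MaterialParameters(K=2.0, mu=0.5, k1=0.1, k2=50.0)
        rng = np.random.default_rng(3)
        a1 = np.array([1.0, 0, 0])
        a2 = np.array([0, 1.0, 0])
        fibers = fem.FiberField(elem_ids=np.array([0]),
                                a1=np.broadcast_to(a1, (1, 8, 3)),
                                a2=np.broadcast_to(a2, (1, 8, 3)),
                                kappa=np.full((1, 8), 0.1))
        asm1 = Assembler(mesh, {"bulk": params}, fiber_field=fibers,
                         fiber_tag="bulk")
        u = 0.08 * rng.standard_normal((8, 3))
        f1 = asm1.internal_force(u.ravel()).reshape(-1, 3)
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        mesh2 = unit_cube_mesh()
        mesh2.nodes = mesh.nodes @ R.T
        fibers2 = fem.FiberField(elem_ids=np.array([0]),
                                 a1=np.broadcast_to(R @ a1, (1, 8, 3)),
                                 a2=np.broadcast_to(R @ a2, (1, 8, 3)),
                                 kappa=np.full((1, 8), 0.1))
        asm2 = Assembler(mesh2, {"bulk": params}, fiber_field=fibers2,
                         fiber_tag="bulk")
        f2 = asm2.internal_force((u @ R.T).ravel()).reshape(-1, 3)
        np.testing.assert_allclose(f2, f1 @ R.T, atol=1e-10)


class TestExternalForces:
    def test_zero_pressure(self):
        mesh, asm = cube_assembler()
        f = asm.external_force(np.zeros(mesh.n_dofs),
                               [PressureLoad("zmax", 0.0)])
        np.testing.assert_allclose(f, 0.0)

    def test_flat_facet_equal_split(self):
        """Unit square facet under pressure p: each node gets p*A/4
        against the outward normal."""
        mesh, asm = cube_assembler()
        p = 0.7
        f = asm.external_force(np.zeros(mesh.n_dofs),
                               [PressureLoad("zmax", p)]).reshape(-1, 3)
        for n in (4, 5, 6, 7):
            np.testing.assert_allclose(f[n], [0, 0, -p / 4.0], atol=1e-13)

    def test_closed_surface_net_force_zero(self):
        mesh, asm = cube_assembler()
        rng = np.random.default_rng(5)
        u = 0.1 * rng.standard_normal(mesh.n_dofs)
        f = asm.external_force(u, [PressureLoad("all", 1.3)]).reshape(-1, 3)
        net = f.sum(axis=0)
        np.testing.assert_allclose(net, 0.0, atol=1e-10 * np.abs(f).max())


class TestFluidCavity:
    def test_cube_cavity_volume(self):
        """Wetted facets oriented into the fluid measure the enclosed
        volume exactly (flat closure/symmetry conventions included)."""
        mesh = unit_cube_mesh()
        inward = {k: v[:, ::-1] for k, v in mesh.facet_sets.items()}
        mesh.facet_sets["wet"] = np.vstack([inward[k] for k in
                                            ("zmin", "zmax", "xmin", "xmax",
                                             "ymin", "ymax")])
        asm = Assembler(mesh, {"bulk": NEO})
        cav = FluidCavity(facet_set="wet", bulk_modulus=2.0, p0=0.1,
                          z_ref=0.0)
        V = asm.cavity_volume(np.zeros(mesh.n_dofs), cav)
        assert V == pytest.approx(1.0, rel=1e-12)
        cav.V0 = V
        _, p = cavity_state(asm, np.zeros(mesh.n_dofs), cav)
        assert p == pytest.approx(0.1)

    def test_sphere_cavity_analytics(self):
        """Octant shell: volume and the linear pressure-volume law match
        the analytic sphere (quadrature error ~ facet curvature)."""
        a = 9.0
        mesh = spherical_shell_octant(a=a, b=10.0, n=8)
        mesh.facet_sets["wet"] = mesh.facet_sets["inner"]
        asm = Assembler(mesh, {"bulk": NEO})
        cav = FluidCavity(facet_set="wet", bulk_modulus=2.0, p0=0.0,
                          z_ref=0.0)
        V0 = asm.cavity_volume(np.zeros(mesh.n_dofs), cav)
        assert V0 == pytest.approx(np.pi * a ** 3 / 6.0, rel=0.02)
        cav.V0 = V0
        # uniform inward radial displacement delta
        delta = 0.01
        ids = np.unique(mesh.facet_sets["inner"])
        u = np.zeros((mesh.n_nodes, 3))
        u -= delta * mesh.nodes / np.linalg.norm(mesh.nodes, axis=1,
                                                 keepdims=True)
        V1, p1 = cavity_state(asm, u.ravel(), cav)
        dV = np.pi * a ** 2 * delta / 2.0        # octant of 4 pi a^2 delta
        assert V0 - V1 == pytest.approx(dV, rel=0.02)
        assert p1 == pytest.approx(2.0 * (V0 - V1) / V0, rel=1e-10)
        # halving the bulk modulus halves the rise exactly
        cav2 = FluidCavity(facet_set="wet", bulk_modulus=1.0, V0=V0,
                           z_ref=0.0)
        assert cavity_state(asm, u.ravel(), cav2)[1] == pytest.approx(
            p1 / 2.0, rel=1e-12)

    def test_volume_gradient_matches_fd(self):
        mesh = spherical_shell_octant(n=4)
        mesh.facet_sets["wet"] = mesh.facet_sets["inner"]
        asm = Assembler(mesh, {"bulk": NEO})
        cav = FluidCavity(facet_set="wet", bulk_modulus=1.0, z_ref=0.0)
        rng = np.random.default_rng(2)
        u = 0.01 * rng.standard_normal(mesh.n_dofs)
        g = asm.cavity_volume_gradient(u, cav)
        d = 1e-6 * rng.standard_normal(mesh.n_dofs)
        dV = (asm.cavity_volume(u + d, cav) - asm.cavity_volume(u - d, cav)) / 2
        assert g @ d == pytest.approx(dV, rel=1e-6)


class TestForwardSolver:
    def test_zero_loads_zero_displacement(self):
        mesh = spherical_shell_octant(n=4)
        asm = Assembler(mesh, {"bulk": NEO})
        u, info = newton_solve(asm, octant_symmetry_bcs(mesh),
                               np.zeros(mesh.n_dofs))
        np.testing.assert_allclose(u, 0.0, atol=1e-12)
        assert info["iterations"] == 0

    def test_lame_thick_wall_sphere(self):
        """Internally pressurised shell vs the Lame solution (<5%)."""
        a, b = 9.0, 10.0
        mesh = spherical_shell_octant(a=a, b=b, n=8, layers=2)
        asm = Assembler(mesh, {"bulk": NEO})
        p = 1e-3                              # small: linear regime
        u, _ = newton_solve(asm, octant_symmetry_bcs(mesh),
                            np.zeros(mesh.n_dofs),
                            loads=[PressureLoad("inner", p)],
                            rtol=1e-10, atol=1e-14)
        E = 9 * NEO.K * NEO.mu / (3 * NEO.K + NEO.mu)
        nu = (3 * NEO.K - 2 * NEO.mu) / (2 * (3 * NEO.K + NEO.mu))

        def lame(r):
            return (p * a ** 3 * r / (E * (b ** 3 - a ** 3))
                    * ((1 - 2 * nu) + (1 + nu) * b ** 3 / (2 * r ** 3)))

        ur = (u.reshape(-1, 3) * mesh.nodes
              / np.linalg.norm(mesh.nodes, axis=1, keepdims=True)).sum(axis=1)
        r = np.linalg.norm(mesh.nodes, axis=1)
        for radius in (a, b):
            sel = np.abs(r - radius) < 1e-6
            assert np.mean(ur[sel]) == pytest.approx(lame(radius), rel=0.05)

    def test_prescribed_displacement_patch(self):
        """Single element driven through Dirichlet data reproduces the
        homogeneous deformation exactly."""
        mesh = unit_cube_mesh()
        asm = Assembler(mesh, {"bulk": NEO})
        lam = 1.1
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        target = mesh.nodes @ (F - np.eye(3)).T
        dofs = np.arange(mesh.n_dofs)
        bcs = BoundaryConditions(prescribed_dofs=dofs,
                                 prescribed_values=target.ravel())
        u, _ = newton_solve(asm, bcs, np.zeros(mesh.n_dofs))
        np.testing.assert_allclose(u, target.ravel(), atol=1e-14)


class TestQuadrature:
    def test_order_insensitivity_on_fixture(self, healthy_model):
        """Apex displacement of the prestressed fixture changes by
        <= 0.1% between 2x2x2 and 3x3x3 Gauss rules."""
        from eyegap.geometry import _prestress_solve
        apex = int(healthy_model.mesh.node_sets["apex_anterior"][0])
        vals = {}
        for order in (2, 3):
            u, _, _ = _prestress_solve(healthy_model, healthy_model.iop,
                                       order=order)
            vals[order] = u.reshape(-1, 3)[apex]
        ref = np.linalg.norm(vals[2])
        assert np.linalg.norm(vals[3] - vals[2]) <= 1e-3 * ref
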