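"""Eye mesh generation, fiber field, and stress-free geometry recovery."""

import numpy as np
import pytest

from eyegap.fem import MMHG_TO_MPA, GeometryError, hex_quadrature
from eyegap.geometry import (AuxiliaryMaterials, EyeGeometryParams,
                             _prestress_solve, build_eye_model,
                             build_fiber_field, stress_free_geometry)
from eyegap.io import material_set

IOP = 17.5 * MMHG_TO_MPA


@pytest.fixture(scope="module")
def model():
    return build_eye_model()


class TestMeshConstruction:
    def test_positive_jacobians(self, model):
        assert model.mesh.check_jacobians() > 0.0

    def test_apex_thickness_matches_cct(self, model):
        axis = np.where(np.hypot(model.mesh.nodes[:, 0],
                                 model.mesh.nodes[:, 1]) < 1e-9)[0]
        z = np.sort(model.mesh.nodes[axis, 2])
        assert z[-1] - z[0] == pytest.approx(model.geometry.cct, abs=1e-6)

    def test_element_sets_partition(self, model):
        ids = np.concatenate(list(model.mesh.elem_sets.values()))
        assert len(ids) == len(model.mesh.elems)
        assert len(np.unique(ids)) == len(ids)

    def test_facets_are_element_faces(self, model):
        """Every anterior facet is a face of some element."""
        mesh = model.mesh
        face_sets = set()
        faces_per_hex = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
                         (3, 2, 6, 7), (0, 3, 7, 4), (1, 2, 6, 5)]
        for e in mesh.elems:
            for f in faces_per_hex:
                face_sets.add(frozenset(e[list(f)]))
        for quad in mesh.facet_sets["anterior"]:
            assert frozenset(quad) in face_sets

    def test_invalid_parameters(self):
        with pytest.raises(GeometryError):
            EyeGeometryParams(cct=-0.1)
        with pytest.raises(GeometryError):
            EyeGeometryParams(limbus_radius=6.0, limbus_width=2.0)
        with pytest.raises(NotImplementedError):
            EyeGeometryParams(include_lens=True)

    def test_cornea_only_variant(self):
        m = build_eye_model(EyeGeometryParams(include_sclera=False))
        assert "sclera" not in m.mesh.elem_sets
        assert m.mesh.check_jacobians() > 0

    def test_limbus_modulus_average_rule(self):
        aux = AuxiliaryMaterials.from_cornea_sclera(E_cornea=0.5)
        assert aux.E_limbus == pytest.approx(0.5 * (0.5 + 2.3))


class TestFiberField:
    def test_unit_norm_and_tangency(self, model):
        ff = model.fiber_field
        for a in (ff.a1, ff.a2):
            np.testing.assert_allclose(np.linalg.norm(a, axis=-1), 1.0,
                                       atol=1e-12)
        # zero component along the local surface normal by construction
        _, _, N, _ = hex_quadrature(2)
        ids = model.mesh.elem_sets["cornea"]
        gp = np.einsum("ga,eai->egi", N, model.mesh.nodes[model.mesh.elems[ids]])
        ax, ay, az = model.geometry.cornea_semiaxes
        nrm = np.stack([gp[..., 0] / ax ** 2, gp[..., 1] / ay ** 2,
                        gp[..., 2] / az ** 2], axis=-1)
        nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)
        assert np.abs(np.einsum("egi,egi->eg", ff.a1, nrm)).max() < 1e-8
        assert np.abs(np.einsum("egi,egi->eg", ff.a2, nrm)).max() < 1e-8

    def test_orthogonal_families_near_apex(self, model):
        ff = model.fiber_field
        _, _, N, _ = hex_quadrature(2)
        ids = model.mesh.elem_sets["cornea"]
        gp = np.einsum("ga,eai->egi", N,
                       model.mesh.nodes[model.mesh.elems[ids]])
        r = np.hypot(gp[..., 0], gp[..., 1])
        dot = np.einsum("egi,egi->eg", ff.a1, ff.a2)
        assert np.abs(dot[r < 0.5]).max() < 1e-3

    def test_constant_kappa_profile(self, model):
        assert np.all(model.fiber_field.kappa == 0.1)

    def test_callable_kappa_profile(self, model):
        ff = build_fiber_field(model.mesh, model.geometry,
                               lambda r: 0.05 + 0.02 * (r / 6.6))
        assert ff.kappa.min() >= 0.05
        assert ff.kappa.max() <= 0.071

    def test_kappa_out_of_range_rejected(self, model):
        with pytest.raises(ValueError):
            build_fiber_field(model.mesh, model.geometry, 0.4)


class TestBoundaryConditions:
    def test_constraint_categories_disjoint(self, model):
        bcs = model.bcs
        assert np.intersect1d(bcs.fixed_dofs, bcs.symmetry_dofs).size == 0

    def test_symmetry_plane_dofs(self, model):
        xsym = np.where(np.abs(model.mesh.nodes[:, 0]) < 1e-9)[0]
        clamped = set(model.bcs.fixed_dofs.tolist())
        sym = set(model.bcs.symmetry_dofs.tolist())
        for n in xsym:
            assert 3 * n in sym or 3 * n in clamped


class TestSymmetryEquivalence:
    def test_quarter_vs_full_under_axisymmetric_load(self):
        """IOP inflation: apex displacement identical between the quarter
        model and the full (unreduced) model."""
        vals = {}
        for mode in ("quarter", "full"):
            m = build_eye_model(EyeGeometryParams(symmetry=mode))
            u, _, _ = _prestress_solve(m, IOP)
            apex = int(m.mesh.node_sets["apex_anterior"][0])
            vals[mode] = u.reshape(-1, 3)[apex]
        assert np.linalg.norm(vals["full"] - vals["quarter"]) <= \
            1e-5 * np.linalg.norm(vals["quarter"]) + 1e-9


class TestStressFreeGeometry:
    def test_zero_iop_identity(self, model):
        sf, info = stress_free_geometry(model.copy(), 0.0)
        assert info["iterations"] == 1
        np.testing.assert_allclose(sf.mesh.nodes, model.mesh.nodes)
        np.testing.assert_allclose(sf.u_pre, 0.0)

    def test_converges_to_2um_and_reloads(self, model, healthy_model):
        """Fixed point: reloading the stress-free mesh at the same IOP
        reproduces the target geometry within the 2 um criterion."""
        target = model.mesh.nodes
        sf = healthy_model
        x = sf.mesh.nodes + sf.u_pre.reshape(-1, 3)
        d = np.linalg.norm(x - target, axis=1)
        assert d.max() <= 2e-3
        # independent reload of the converged stress-free mesh
        u, _, _ = _prestress_solve(sf, IOP)
        x2 = sf.mesh.nodes + u.reshape(-1, 3)
        assert np.linalg.norm(x2 - target, axis=1).max() <= 2e-3

    def test_prestressed_cavity_pressure_anchored(self, healthy_model):
        asm = healthy_model.assembler()
        cav = healthy_model.cavities[0]
        V, p = asm.cavity_volume(healthy_model.u_pre, cav), None
        p = cav.pressure(V)
        assert p == pytest.approx(IOP, rel=1e-9)

    def test_negative_iop_rejected(self, model):
        with pytest.raises(ValueError):
            stress_free_geometry(model, -1.0)

    def test_mesh_refinement_stability(self):
        """Doubling the in-plane density moves the prestressed apex by
        < 1%."""
        apexes = {}
        for n, nt in ((8, 2), (12, 3)):
            m = build_eye_model(EyeGeometryParams(n_inplane=n,
                                                  n_thickness=nt,
                                                  n_sclera=6 if n == 8 else 9))
            u, _, _ = _prestress_solve(m, IOP)
            apex = int(m.mesh.node_sets["apex_anterior"][0])
            apexes[n] = m.mesh.nodes[apex] + u.reshape(-1, 3)[apex]
        assert np.linalg.norm(apexes[12] - apexes[8]) < 0.01 * \
            np.linalg.norm(apexes[8])
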