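"""Shared fixtures: prestressed eye models and reference tonometry records.

Everything heavy (stress-free geometry, forward tonometry runs) is
session-scoped and generated once; all fixtures are deterministic.
"""

import numpy as np
import pytest

from eyegap.fem import MMHG_TO_MPA, BoundaryConditions, Mesh, hex_quadrature
from eyegap.geometry import build_eye_model, stress_free_geometry
from eyegap.io import material_set
from eyegap.nct import run_virtual_nct

IOP = 17.5 * MMHG_TO_MPA
MATERIAL_TAGS = ("H", "KK-I", "KK-II", "KK-III")


@pytest.fixture(scope="session")
def prestressed_models():
    """Prestressed eye models for all four reference parameter sets."""
    out = {}
    for tag in MATERIAL_TAGS:
        model = build_eye_model(cornea=material_set(tag))
        out[tag], _ = stress_free_geometry(model, IOP)
    return out


@pytest.fixture(scope="session")
def records(prestressed_models):
    """Virtual tonometry records (3 states each) for all four sets."""
    return {tag: run_virtual_nct(model, material_tag=tag)
            for tag, model in prestressed_models.items()}


@pytest.fixture(scope="session")
def healthy_model(prestressed_models):
    return prestressed_models["H"]


@pytest.fixture(scope="session")
def healthy_record(records):
    return records["H"]


# ---------------------------------------------------------------------------
# small analytic meshes for the FEM unit tests


def unit_cube_mesh():
    """Single unit-cube hex element with face facet sets (outward)."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                     dtype=float)
    elems = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    faces = {
        "zmin": [[0, 3, 2, 1]],
        "zmax": [[4, 5, 6, 7]],
        "ymin": [[0, 1, 5, 4]],
        "ymax": [[3, 7, 6, 2]],
        "xmin": [[0, 4, 7, 3]],
        "xmax": [[1, 2, 6, 5]],
    }
    mesh = Mesh(nodes=nodes, elems=elems,
                elem_sets={"bulk": np.array([0])},
                facet_sets={k: np.array(v) for k, v in faces.items()})
    mesh.facet_sets["all"] = np.vstack(list(faces.values()))
    return mesh


def spherical_shell_octant(a=9.0, b=10.0, n=6, layers=2):
    """Octant of a thick-walled spherical shell (hex8, polar-singularity
    free via the square-to-disc mapping composed with the azimuthal
    equidistant projection)."""
    sv = np.linspace(0.0, 1.0, n + 1)
    S, T = np.meshgrid(sv, sv, indexing="ij")
    px = S * np.sqrt(1 - 0.5 * T ** 2)
    py = T * np.sqrt(1 - 0.5 * S ** 2)
    rho = np.hypot(px, py)
    theta = np.arctan2(py, px)
    phi = rho * (np.pi / 2.0)

    radii = np.linspace(a, b, layers + 1)
    nid = np.empty((n + 1, n + 1, layers + 1), dtype=int)
    nodes = []
    for i in range(n + 1):
        for j in range(n + 1):
            d = np.array([np.sin(phi[i, j]) * np.cos(theta[i, j]),
                          np.sin(phi[i, j]) * np.sin(theta[i, j]),
                          np.cos(phi[i, j])])
            for k, R in enumerate(radii):
                nid[i, j, k] = len(nodes)
                nodes.append(R * d)
    elems, inner, outer = [], [], []
    for i in range(n):
        for j in range(n):
            for k in range(layers):
                elems.append([nid[i, j, k], nid[i + 1, j, k],
                              nid[i + 1, j + 1, k], nid[i, j + 1, k],
                              nid[i, j, k + 1], nid[i + 1, j, k + 1],
                              nid[i + 1, j + 1, k + 1], nid[i, j + 1, k + 1]])
            inner.append([nid[i, j, 0], nid[i, j + 1, 0],
                          nid[i + 1, j + 1, 0], nid[i + 1, j, 0]])
            outer.append([nid[i, j, layers], nid[i + 1, j, layers],
                          nid[i + 1, j + 1, layers], nid[i, j + 1, layers]])
    mesh = Mesh(nodes=np.array(nodes), elems=np.array(elems),
                elem_sets={"bulk": np.arange(len(elems))},
                facet_sets={"inner": np.array(inner),
                            "outer": np.array(outer)})
    assert mesh.check_jacobians() > 0
    return mesh


def octant_symmetry_bcs(mesh, tol=1e-9):
    dofs = []
    for axis in range(3):
        ids = np.where(np.abs(mesh.nodes[:, axis]) < tol)[0]
        dofs.append(3 * ids + axis)
    return BoundaryConditions(symmetry_dofs=np.unique(np.concatenate(dofs)))


def random_states(n, seed, spread=0.15, jmin=0.9, jmax=1.2):
    """Random deformation gradients with det(F) uniform in [jmin, jmax]."""
    rng = np.random.default_rng(seed)
    F = np.eye(3) + spread * rng.uniform(-1, 1, size=(n, 3, 3))
    J = np.linalg.det(F)
    # reject grossly distorted draws, then rescale the volume exactly
    ok = J > 0.3
    F = F[ok]
    Jt = rng.uniform(jmin, jmax, size=F.shape[0])
    F *= (Jt / np.linalg.det(F))[:, None, None] ** (1.0 / 3.0)
    return F
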