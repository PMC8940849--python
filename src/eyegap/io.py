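"""Formats, configuration and persistence.

* reference material parameter sets (healthy and three keratoconus-like
  degradations of the fiber stiffness) used throughout the studies;
* record bundles: a directory of JSON metadata + full-precision CSV
  arrays (%.17g round-trips IEEE doubles bit-exactly);
* a JSON mesh schema and a legacy-ASCII VTK unstructured-grid writer /
  reader for meshes and nodal fields;
* YAML study configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Dict, Optional

import numpy as np
import yaml

from .constitutive import MaterialParameters
from .fem import MMHG_TO_MPA, FluidCavity, Mesh
from .geometry import (AuxiliaryMaterials, EyeGeometryParams, EyeModel,
                       build_eye_model, build_fiber_field)
from .nct import ContourPair, NCTRecord, PulseLoad

__all__ = [
    "MATERIAL_SETS",
    "material_set",
    "save_record",
    "load_record",
    "mesh_to_json",
    "mesh_from_json",
    "write_vtk",
    "read_vtk",
    "save_contour_csv",
    "load_contour_csv",
    "default_config",
    "load_config",
    "model_from_config",
    "MMHG_TO_MPA",
]

SCHEMA_VERSION = "1"

#: reference (healthy) set and fiber-stiffness degradations; K, mu, k1 in
#: MPa, k2 dimensionless
MATERIAL_SETS: Dict[str, Dict[str, float]] = {
    "H":      {"K": 10.0, "mu": 0.275, "k1": 0.04, "k2": 200.0},
    "KK-I":   {"K": 10.0, "mu": 0.275, "k1": 0.02, "k2": 200.0},
    "KK-II":  {"K": 10.0, "mu": 0.275, "k1": 0.01, "k2": 200.0},
    "KK-III": {"K": 10.0, "mu": 0.275, "k1": 0.00, "k2": 200.0},
}


def material_set(name: str, **overrides) -> MaterialParameters:
    """Reference MaterialParameters by set name (H, KK-I, KK-II, KK-III)."""
    if name not in MATERIAL_SETS:
        raise KeyError(f"unknown material set '{name}'; "
                       f"known: {sorted(MATERIAL_SETS)}")
    kw = dict(MATERIAL_SETS[name])
    kw.update(overrides)
    return MaterialParameters(**kw)


# ---------------------------------------------------------------------------
# array helpers: text CSV that round-trips doubles exactly


def _save_array(path: str, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt="%.17g", delimiter=",")


def _load_array(path: str) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


# ---------------------------------------------------------------------------
# mesh JSON schema


def mesh_to_json(mesh: Mesh) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "nodes": mesh.nodes.tolist(),
        "elems": mesh.elems.tolist(),
        "elem_sets": {k: v.tolist() for k, v in mesh.elem_sets.items()},
        "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
        "facet_sets": {k: v.tolist() for k, v in mesh.facet_sets.items()},
    }


def mesh_from_json(data: dict) -> Mesh:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise IOError(f"mesh schema version mismatch: "
                      f"{data.get('schema_version')!r} != {SCHEMA_VERSION!r}")
    return Mesh(
        nodes=np.array(data["nodes"], dtype=float),
        elems=np.array(data["elems"], dtype=int),
        elem_sets={k: np.array(v, dtype=int)
                   for k, v in data["elem_sets"].items()},
        node_sets={k: np.array(v, dtype=int)
                   for k, v in data["node_sets"].items()},
        facet_sets={k: np.array(v, dtype=int)
                    for k, v in data["facet_sets"].items()},
    )


# ---------------------------------------------------------------------------
# contours


def save_contour_csv(path: str, contours: ContourPair) -> None:
    with open(path, "w") as fh:
        fh.write("surface,r_mm,z_mm\n")
        for tag, arr in (("anterior", contours.anterior),
                         ("posterior", contours.posterior)):
            for r, z in arr:
                fh.write(f"{tag},{r:.17g},{z:.17g}\n")


def load_contour_csv(path: str, defa: float = 0.0, cct: float = 0.0,
                     iop: float = 0.0) -> ContourPair:
    """Read a contour CSV; rows are re-sorted by radius deterministically."""
    rows = {"anterior": [], "posterior": []}
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != ["surface", "r_mm", "z_mm"]:
            raise IOError(f"unexpected contour CSV header: {header}")
        for line in fh:
            tag, r, z = line.strip().split(",")
            rows[tag].append((float(r), float(z)))
    out = {}
    for tag, pts in rows.items():
        arr = np.array(sorted(pts), dtype=float)
        out[tag] = arr
    return ContourPair(anterior=out["anterior"], posterior=out["posterior"],
                       defa=defa, cct=cct, iop=iop)


# ---------------------------------------------------------------------------
# record bundle


def save_record(record: NCTRecord, path: str) -> None:
    """Persist a tonometry record as a directory bundle (JSON + CSV)."""
    os.makedirs(path, exist_ok=True)
    model = record.model
    cav = model.cavities[0]
    meta = {
        "schema_version": SCHEMA_VERSION,
        "material_tag": record.material_tag,
        "seed": record.seed,
        "iop": model.iop,
        "pulse": {"peak": record.pulse.peak, "width": record.pulse.width,
                  "ramp": list(map(float, record.pulse.ramp))},
        "state_indices": list(record.state_indices),
        "state_load_factors": record.state_load_factors.tolist(),
        "cavity": {"facet_set": cav.facet_set, "V0": cav.V0, "p0": cav.p0,
                   "bulk_modulus": cav.bulk_modulus, "z_ref": cav.z_ref},
        "geometry": dataclasses.asdict(model.geometry),
        "aux": dataclasses.asdict(model.aux),
        "cornea": dataclasses.asdict(model.materials["cornea"]),
        "kappa": (model.kappa_profile
                  if not callable(model.kappa_profile) else None),
        "contour_meta": [
            {"defa": c.defa, "cct": c.cct, "iop": c.iop}
            for c in [record.contour_reference] + record.contours],
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(os.path.join(path, "mesh.json"), "w") as fh:
        json.dump(mesh_to_json(model.mesh), fh)
    _save_array(os.path.join(path, "displacements.csv"), record.displacements)
    _save_array(os.path.join(path, "u_pre.csv"), model.u_pre)
    _save_array(os.path.join(path, "u_states.csv"), record.u_states)
    _save_array(os.path.join(path, "f_ext_states.csv"), record.f_ext_states)
    _save_array(os.path.join(path, "cavity_pressures.csv"),
                record.cavity_pressures)
    _save_array(os.path.join(path, "state_cavity_pressures.csv"),
                record.state_cavity_pressures)
    _save_array(os.path.join(path, "defa_trace.csv"), record.defa_trace)
    _save_array(os.path.join(path, "load_factors.csv"), record.load_factors)
    save_contour_csv(os.path.join(path, "contours_reference.csv"),
                     record.contour_reference)
    for i, c in enumerate(record.contours):
        save_contour_csv(os.path.join(path, f"contours_state{i + 1}.csv"), c)


def load_record(path: str) -> NCTRecord:
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise IOError(f"not a record bundle: missing {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise IOError(f"record schema version mismatch: "
                      f"{meta.get('schema_version')!r} != {SCHEMA_VERSION!r}")
    with open(os.path.join(path, "mesh.json")) as fh:
        mesh = mesh_from_json(json.load(fh))

    geometry = EyeGeometryParams(**{
        **meta["geometry"],
        "cornea_semiaxes": tuple(meta["geometry"]["cornea_semiaxes"])})
    aux = AuxiliaryMaterials(**meta["aux"])
    cornea = MaterialParameters(**meta["cornea"])
    kappa = meta["kappa"] if meta["kappa"] is not None else 0.1
    cav = FluidCavity(**meta["cavity"])

    from .geometry import make_boundary_conditions
    bcs = make_boundary_conditions(mesh, geometry.symmetry)
    fiber = build_fiber_field(mesh, geometry, kappa)
    model = EyeModel(mesh=mesh, materials={"cornea": cornea}, bcs=bcs,
                     fiber_field=fiber, cavities=[cav], geometry=geometry,
                     aux=aux, kappa_profile=kappa, iop=meta["iop"])
    from .constitutive import elastic_to_hyperelastic
    model.materials["limbus"] = elastic_to_hyperelastic(aux.E_limbus, aux.nu)
    if "sclera" in mesh.elem_sets:
        model.materials["sclera"] = elastic_to_hyperelastic(aux.E_sclera,
                                                            aux.nu)
    model.u_pre = _load_array(os.path.join(path, "u_pre.csv")).ravel()

    def arr(name, flat=False):
        a = _load_array(os.path.join(path, name))
        return a.ravel() if flat else a

    needed = ["u_states.csv", "f_ext_states.csv", "displacements.csv"]
    for n in needed:
        if not os.path.exists(os.path.join(path, n)):
            raise IOError(f"record bundle missing state data: {n}")
    cm = meta["contour_meta"]
    contour_ref = load_contour_csv(
        os.path.join(path, "contours_reference.csv"), **cm[0])
    contours = [load_contour_csv(
        os.path.join(path, f"contours_state{i + 1}.csv"), **cm[i + 1])
        for i in range(3)]
    pulse = PulseLoad(**meta["pulse"])
    return NCTRecord(
        model=model, pulse=pulse,
        load_factors=arr("load_factors.csv", flat=True),
        displacements=arr("displacements.csv"),
        cavity_pressures=arr("cavity_pressures.csv", flat=True),
        defa_trace=arr("defa_trace.csv", flat=True),
        state_indices=tuple(meta["state_indices"]),
        u_states=arr("u_states.csv"),
        f_ext_states=arr("f_ext_states.csv"),
        state_cavity_pressures=arr("state_cavity_pressures.csv", flat=True),
        state_load_factors=np.array(meta["state_load_factors"]),
        contours=contours, contour_reference=contour_ref,
        material_tag=meta["material_tag"], seed=meta["seed"])


# ---------------------------------------------------------------------------
# VTK legacy ASCII


def write_vtk(path: str, mesh: Mesh,
              point_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the mesh (and nodal fields) as a legacy-ASCII VTK file."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("eyegap unstructured grid\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        E = len(mesh.elems)
        fh.write(f"CELLS {E} {9 * E}\n")
        for e in mesh.elems:
            fh.write("8 " + " ".join(map(str, e)) + "\n")
        fh.write(f"CELL_TYPES {E}\n")
        fh.write("\n".join(["12"] * E) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\n")
                    fh.write("LOOKUP_TABLE default\n")
                    for v in arr.ravel():
                        fh.write(f"{v:.17g}\n")


def read_vtk(path: str) -> Mesh:
    """Read a legacy-ASCII VTK unstructured grid written by write_vtk."""
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        return tokens.index(word)
    i = find("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = find("CELLS")
    ne = int(tokens[i + 1])
    raw = np.array(tokens[i + 3:i + 3 + 9 * ne], dtype=int).reshape(ne, 9)
    if not np.all(raw[:, 0] == 8):
        raise IOError("only hex8 cells are supported")
    return Mesh(nodes=pts, elems=raw[:, 1:],
                elem_sets={"all": np.arange(ne)})


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    return {
        "geometry": dataclasses.asdict(EyeGeometryParams()),
        "aux": dataclasses.asdict(AuxiliaryMaterials()),
        "material_set": "H",
        "kappa": 0.1,
        "iop_mmHg": 17.5,
        "pulse": {"peak": PulseLoad().peak, "width": PulseLoad().width,
                  "ramp": list(map(float, PulseLoad().ramp))},
        "k2_grid": {"min": 10.0, "max": 400.0, "step": 10.0},
        "noise": {"amplitudes": [1e-5, 1e-4], "repetitions": 10},
        "seed": 0,
    }


def load_config(path: Optional[str]) -> dict:
    cfg = default_config()
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def model_from_config(cfg: dict, material_tag: Optional[str] = None) -> EyeModel:
    geom = dict(cfg["geometry"])
    geom["cornea_semiaxes"] = tuple(geom["cornea_semiaxes"])
    params = EyeGeometryParams(**geom)
    aux = AuxiliaryMaterials(**cfg["aux"])
    tag = material_tag or cfg.get("material_set", "H")
    cornea = material_set(tag)
    return build_eye_model(params, cornea=cornea, aux=aux,
                           kappa_profile=cfg.get("kappa", 0.1))
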