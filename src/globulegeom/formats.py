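"""File-format adapters: STAR pose tables, MRC density grids, PDB models.

STAR tables use explicit ``_pose*`` tags plus a ``_poseEulerConvention``
item stating the angle convention (intrinsic XYZ, degrees) so the table is
self-describing; conversion from other Euler conventions is an explicit
utility, never implicit.  MRC I/O goes through gemmi's CCP4 map support
with the voxel size carried in the unit cell and the origin in header words
50–52.  Rigid pseudo-atom models round-trip as PDB with marker labels and
the symmetry operator in a JSON sidecar (PDB has no field for either).
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .particle_morphology import DensityGrid
from .pose_geometry import (
    CrosslinkSet,
    Pose,
    RigidModel,
    euler_from_matrix,
    matrix_from_euler,
)

__all__ = [
    "EULER_CONVENTION",
    "read_pose_table",
    "write_pose_table",
    "read_density",
    "write_density",
    "read_point_model",
    "write_point_model",
    "read_crosslink_csv",
    "convert_euler_convention",
]

EULER_CONVENTION = "intrinsic-XYZ-deg"

_POSE_TAGS = [
    "_poseCoordinateX", "_poseCoordinateY", "_poseCoordinateZ",
    "_poseAngleRotX", "_poseAngleRotY", "_poseAngleRotZ",
    "_poseTomogramID", "_poseParticleID",
]


def write_pose_table(poses: list[Pose], path: str | Path) -> None:
    """Write poses as a STAR particle table (coordinates Å, angles degrees)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    block.set_pair("_poseEulerConvention", gemmi.cif.quote(EULER_CONVENTION))
    loop = block.init_loop("", _POSE_TAGS)
    for pose in poses:
        rx, ry, rz = euler_from_matrix(pose.rotation)
        pid = "" if pose.particle_id is None else str(pose.particle_id)
        loop.add_row([
            f"{pose.center[0]:.6f}", f"{pose.center[1]:.6f}", f"{pose.center[2]:.6f}",
            f"{rx:.8f}", f"{ry:.8f}", f"{rz:.8f}",
            gemmi.cif.quote(pose.tomogram_id), gemmi.cif.quote(pid),
        ])
    Path(path).write_text(doc.as_string())


def read_pose_table(path: str | Path) -> list[Pose]:
    """Read a STAR particle table back into poses.

    Angle columns are interpreted in the documented intrinsic-XYZ degree
    convention and converted to rotation matrices.  A missing required
    column raises an error naming it.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    conv = block.find_value("_poseEulerConvention")
    if conv is not None and gemmi.cif.as_string(conv) != EULER_CONVENTION:
        raise ValueError(
            f"pose table declares convention {conv}, expected {EULER_CONVENTION}; "
            "convert with convert_euler_convention() first"
        )
    cols = {}
    for tag in _POSE_TAGS:
        col = block.find_loop(tag)
        vals = list(col)
        if not vals and tag not in ("_poseTomogramID", "_poseParticleID"):
            raise ValueError(f"pose table is missing required column {tag}")
        cols[tag] = vals
    n = len(cols["_poseCoordinateX"])
    poses = []
    for i in range(n):
        angles = [float(cols[f"_poseAngleRot{ax}"][i]) for ax in "XYZ"]
        center = [float(cols[f"_poseCoordinate{ax}"][i]) for ax in "XYZ"]
        tomo = (
            gemmi.cif.as_string(cols["_poseTomogramID"][i])
            if cols["_poseTomogramID"] else "tomo_0"
        )
        pid_raw = (
            gemmi.cif.as_string(cols["_poseParticleID"][i])
            if cols["_poseParticleID"] else ""
        )
        poses.append(Pose(
            rotation=matrix_from_euler(angles),
            center=center,
            tomogram_id=tomo,
            particle_id=int(pid_raw) if pid_raw != "" else None,
        ))
    return poses


def poses_to_csv(poses: list[Pose], path: str | Path) -> None:
    rows = []
    for pose in poses:
        rx, ry, rz = euler_from_matrix(pose.rotation)
        rows.append({
            "x": pose.center[0], "y": pose.center[1], "z": pose.center[2],
            "rotX": rx, "rotY": ry, "rotZ": rz,
            "tomogram_id": pose.tomogram_id, "particle_id": pose.particle_id,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def convert_euler_convention(
    angles: np.ndarray, order: str, degrees: bool = True
) -> np.ndarray:
    """Convert Euler angles from another scipy-style order (e.g. 'ZYZ',
    'zyz') to this package's intrinsic-XYZ degrees."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler(order, np.atleast_2d(angles), degrees=degrees)
    return R.as_euler("XYZ", degrees=True)


# ---------------------------------------------------------------------------
# MRC

def write_density(grid: DensityGrid, path: str | Path) -> None:
    """Write a DensityGrid as an MRC/CCP4 map (voxel size in the cell,
    origin in header words 50–52, Å)."""
    nx, ny, nz = grid.values.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(g)[:] = grid.values
    g.set_unit_cell(gemmi.UnitCell(
        nx * grid.voxel_size, ny * grid.voxel_size, nz * grid.voxel_size, 90, 90, 90
    ))
    g.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def read_density(path: str | Path) -> DensityGrid:
    """Read an MRC/CCP4 map; voxel size from the header cell."""
    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True)
    spacing = m.grid.spacing
    if not np.allclose(spacing, spacing[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxel size {spacing} not supported")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityGrid(values, float(spacing[0]), origin)


# ---------------------------------------------------------------------------
# PDB pseudo-atom models

def write_point_model(model: RigidModel, path: str | Path) -> None:
    """Write a rigid model as PDB pseudo-atoms (CA per residue) plus a JSON
    sidecar (<path>.json) holding markers and the symmetry operator."""
    st = gemmi.Structure()
    st.name = "pseudo-atom model"
    gm = gemmi.Model("1")
    for chain_name in dict.fromkeys(model.chains):
        chain = gemmi.Chain(chain_name)
        for i, (c, resi) in enumerate(zip(model.chains, model.residues)):
            if c != chain_name:
                continue
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(resi), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*model.coords[i])
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
    sidecar = {
        "labels": model.labels,
        "center_marker": model.center_marker,
        "symmetry_pair": list(model.symmetry_pair),
        "symmetry_op": np.asarray(model.symmetry_op).tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_point_model(path: str | Path) -> RigidModel:
    """Read a PDB pseudo-atom model written by :func:`write_point_model`."""
    st = gemmi.read_structure(str(path))
    chains, residues, coords = [], [], []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                chains.append(chain.name)
                residues.append(res.seqid.num)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"marker sidecar {sidecar_path} not found; PDB alone does not "
            "identify the center/symmetry markers"
        )
    meta = json.loads(sidecar_path.read_text())
    return RigidModel(
        labels=list(meta["labels"]),
        chains=chains,
        residues=residues,
        coords=np.asarray(coords, float),
        center_marker=meta["center_marker"],
        symmetry_pair=tuple(meta["symmetry_pair"]),
        symmetry_op=np.asarray(meta["symmetry_op"], float),
    )


def read_crosslink_csv(path: str | Path) -> CrosslinkSet:
    """Read crosslinks from CSV with columns chainA,resA,chainB,resB
    (1-based residue numbers matching the PDB)."""
    df = pd.read_csv(path)
    required = ["chainA", "resA", "chainB", "resB"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"crosslink CSV is missing required column {col!r}")
    pairs = [
        (str(r.chainA), int(r.resA), str(r.chainB), int(r.resB))
        for r in df.itertuples()
    ]
    return CrosslinkSet(pairs=pairs)
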