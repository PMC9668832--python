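"""Structure handling for dynamics analysis of C2-symmetric homodimers.

Three jobs: extract unit backbone amide N-H vectors from a PDB structure
(constructing the amide proton in the peptide plane when it is absent),
rigidly re-orient a homodimer so its C2 symmetry axis lies on +z (the
frame required by the four-parameter diffusion tensor), and write
per-residue scalar maps (S2, Rex, CSP) into the B-factor column for
visualisation.

Residue ids are chain-qualified, e.g. ``"A:57"``, with numbering taken
verbatim from the source file.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

BACKBONE = ("N", "CA", "C")
NH_BOND_LENGTH = 1.02  # Angstrom, for constructed amide protons


@dataclass
class StructureFrame:
    """A structure plus its derived N-H unit vectors.

    ``nh_vectors`` maps chain-qualified residue ids to unit vectors;
    ``skipped`` records residues for which no vector could be derived
    (prolines, chain starts, missing backbone atoms) with the reason.
    """

    structure: gemmi.Structure
    nh_vectors: dict[str, np.ndarray] = dc_field(default_factory=dict)
    skipped: dict[str, str] = dc_field(default_factory=dict)
    provenance: str = ""


def _residue_atoms(residue: gemmi.Residue) -> dict[str, np.ndarray]:
    """Atom name -> position, taking the highest-occupancy altloc."""
    best: dict[str, tuple[float, np.ndarray]] = {}
    for atom in residue:
        occ = atom.occ if atom.occ > 0 else 1.0
        if atom.name not in best or occ > best[atom.name][0]:
            best[atom.name] = (occ, np.array(atom.pos.tolist()))
    return {k: v[1] for k, v in best.items()}


def construct_amide_H(N: np.ndarray, CA: np.ndarray, C_prev: np.ndarray) -> np.ndarray:
    """Place the amide H in the peptide plane, opposite the bisector of
    the C(i-1)->N and CA->N directions, at 1.02 A from N."""
    u1 = (C_prev - N) / np.linalg.norm(C_prev - N)
    u2 = (CA - N) / np.linalg.norm(CA - N)
    bis = u1 + u2
    h_dir = -bis / np.linalg.norm(bis)
    return N + NH_BOND_LENGTH * h_dir


def read_structure(path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def nh_vectors(structure: gemmi.Structure, model_index: int = 0) -> StructureFrame:
    """Unit N->H vectors for every amide in the structure.

    The explicit amide proton (H, HN or NH) is used when present;
    otherwise it is constructed in the peptide plane.  Prolines and chain
    starts (no preceding carbonyl) are skipped and reported.
    """
    frame = StructureFrame(structure=structure, provenance=structure.name)
    model = structure[model_index]
    for chain in model:
        residues = list(chain)
        for i, res in enumerate(residues):
            rid = f"{chain.name}:{res.seqid.num}"
            atoms = _residue_atoms(res)
            if "N" not in atoms:
                frame.skipped[rid] = "missing backbone N"
                continue
            if res.name == "PRO":
                frame.skipped[rid] = "proline (no amide H)"
                continue
            H = None
            for name in ("H", "HN", "NH"):
                if name in atoms:
                    H = atoms[name]
                    break
            if H is None:
                if i == 0:
                    frame.skipped[rid] = "chain start (no preceding carbonyl)"
                    continue
                prev = _residue_atoms(residues[i - 1])
                if "C" not in prev or "CA" not in atoms:
                    frame.skipped[rid] = "cannot construct H (missing C(i-1) or CA)"
                    continue
                H = construct_amide_H(atoms["N"], atoms["CA"], prev["C"])
            v = H - atoms["N"]
            frame.nh_vectors[rid] = v / np.linalg.norm(v)
    return frame


# ---------------------------------------------------------------------------
# C2 alignment
# ---------------------------------------------------------------------------


def _backbone_coords(model: gemmi.Model, chain_name: str) -> dict[tuple[int, str], np.ndarray]:
    out = {}
    for chain in model:
        if chain.name != chain_name:
            continue
        for res in chain:
            atoms = _residue_atoms(res)
            for name in BACKBONE:
                if name in atoms:
                    out[(res.seqid.num, name)] = atoms[name]
    return out


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation R and translation t with R @ p + t ~ q."""
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - Qc, P - Pc)
    R = rot.as_matrix()
    t = Qc - R @ Pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class C2Alignment:
    """Report of a C2 alignment: transform applied and diagnostics."""

    rotation: np.ndarray  # 3x3 applied to all atoms
    origin: np.ndarray  # point subtracted before rotating
    axis: np.ndarray  # recovered C2 axis (unit, original coordinates)
    angle_deg: float  # rotation angle of the A->B superposition
    rmsd: float  # backbone RMSD of the superposition


def align_c2(
    structure: gemmi.Structure,
    chain_pair: tuple[str, str] = ("A", "B"),
    max_angle_dev: float = 15.0,
    force: bool = False,
    model_index: int = 0,
) -> C2Alignment:
    """Rotate a homodimer (in place) so its C2 axis lies on +z.

    Chain A is superposed onto chain B over shared backbone atoms; the
    rotation axis of that transform is the dimer's symmetry axis.  The
    assembly is then rotated about the axis point so the axis becomes +z.
    Refuses (unless ``force``) when the superposition angle deviates from
    180 degrees by more than ``max_angle_dev``.
    """
    model = structure[model_index]
    ca, cb = chain_pair
    A = _backbone_coords(model, ca)
    B = _backbone_coords(model, cb)
    shared = sorted(set(A) & set(B))
    if len(shared) < 3:
        raise ValueError(f"chains {ca}/{cb} share fewer than 3 backbone atoms")
    P = np.stack([A[k] for k in shared])
    Q = np.stack([B[k] for k in shared])
    R, t, rmsd = _kabsch(P, Q)

    rot = Rotation.from_matrix(R)
    rv = rot.as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rv)))
    if abs(angle - 180.0) > max_angle_dev and not force:
        raise ValueError(
            f"A->B rotation is {angle:.1f} deg, deviating from 180 by more "
            f"than {max_angle_dev} deg: not C2-symmetric (use force=True to override)"
        )
    axis = rv / np.linalg.norm(rv)
    # canonical axis representative: +z hemisphere (axis and -axis are the same line)
    if axis[2] < 0 or (axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
    # a point on the rotation axis: least-squares solution of (I - R) p = t
    p0, *_ = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)

    # rotation carrying the axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        Q_align = np.eye(3) if c > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    else:
        Q_align = Rotation.from_rotvec(v / s * np.arctan2(s, c)).as_matrix()

    for chain in model:
        for res in chain:
            for atom in res:
                x = np.array(atom.pos.tolist())
                y = Q_align @ (x - p0)
                atom.pos = gemmi.Position(*y)
    return C2Alignment(rotation=Q_align, origin=p0, axis=axis, angle_deg=angle, rmsd=rmsd)


# ---------------------------------------------------------------------------
# value maps
# ---------------------------------------------------------------------------


@dataclass
class ResidueValueMap:
    """Per-residue scalar (S2, Rex, CSP, ...) destined for the B column."""

    kind: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.kind:
            raise ValueError("value kind must be recorded")
        bad = {k: v for k, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite values for residues: {sorted(bad)}")


def write_value_map(
    structure: gemmi.Structure,
    values: ResidueValueMap,
    pdb_out,
    sidecar_out=None,
    model_index: int = 0,
) -> pd.DataFrame:
    """Write a copy of the structure with values min-max scaled into B-factors.

    Values are scaled to [0, 99.99] (the fixed-column PDB B-factor range
    at two decimals); the exact mapping is returned and optionally written
    as a sidecar TSV so no information is lost.  Residues without a value
    get B = 0.00 and are listed in the sidecar with ``scaled = NaN``.
    """
    vals = values.values
    if vals:
        vmin = min(vals.values())
        vmax = max(vals.values())
    else:
        vmin = vmax = 0.0
    span = vmax - vmin

    def scale(v: float) -> float:
        if span == 0:
            return 0.0 if vmin == 0 else 99.99
        return round((v - vmin) / span * 99.99, 2)

    rows = []
    model = structure[model_index]
    for chain in model:
        for res in chain:
            rid = f"{chain.name}:{res.seqid.num}"
            if rid in vals:
                b = scale(vals[rid])
                rows.append({"residue_id": rid, "kind": values.kind,
                             "value": vals[rid], "scaled": b})
            else:
                b = 0.0
                rows.append({"residue_id": rid, "kind": values.kind,
                             "value": np.nan, "scaled": np.nan})
            for atom in res:
                atom.b_iso = b
    structure.write_pdb(str(pdb_out))
    table = pd.DataFrame(rows)
    if sidecar_out is not None:
        with open(sidecar_out, "w") as fh:
            fh.write(f"# kind={values.kind} vmin={vmin:g} vmax={vmax:g} "
                     "scaled = (value - vmin)/(vmax - vmin)*99.99\n")
            table.to_csv(fh, sep="\t", index=False)
    return table
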