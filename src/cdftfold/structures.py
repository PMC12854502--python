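"""Protein structures and geometric metrics.

Reads fixed-column PDB text into :class:`MolecularStructure`, computes
backbone dihedral angles, and provides the structural metrics that
reactivity descriptors are compared against: Kabsch-superposed RMSD over
Cα atoms, per-residue RMSF, and the fraction of native contacts Q.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularStructure",
    "DihedralTable",
    "read_structure",
    "write_pdb",
    "backbone_dihedrals",
    "dihedral_angle",
    "kabsch_superpose",
    "rmsd_ca",
    "rmsf_ca",
    "native_contacts_q",
]

# Residue names flagged as solvent/ion rather than polymer.
_SOLVENT_NAMES = {"HOH", "WAT", "SOL", "DOD", "NA", "CL", "K", "MG", "ZN",
                  "CA", "MN", "FE", "BR", "IOD", "SO4", "PO4"}

_TWO_LETTER_ELEMENTS = {
    "He", "Li", "Be", "Ne", "Na", "Mg", "Al", "Si", "Cl", "Ar", "Ca",
    "Fe", "Zn", "Mn", "Cu", "Ni", "Co", "Se", "Br", "Mo", "Cd",
}


@dataclass
class MolecularStructure:
    """Atoms with Cartesian coordinates (Å) and residue assignment.

    ``residue_index[i]`` maps atom ``i`` to a residue; residues carry a
    3-letter name, a sequence number (with any insertion code appended),
    and a chain id.
    """

    elements: list[str]
    coords: np.ndarray                # (n_atoms, 3) in Å
    atom_names: list[str]
    residue_index: np.ndarray         # (n_atoms,) int
    residue_names: list[str]          # per residue
    residue_seq: list[str]            # per residue, seq number + icode
    residue_chain: list[str]          # per residue
    is_solvent: np.ndarray = field(default=None)  # per atom bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.is_solvent is None:
            self.is_solvent = np.zeros(len(self.elements), dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coordinate array shape mismatch")
        if len(self.residue_index) != len(self.elements):
            raise ValueError("residue assignment length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def residue_labels(self) -> list[str]:
        """Unique labels of the form ``chain:NAMEseq``."""
        return [
            f"{c}:{n}{s}"
            for n, s, c in zip(self.residue_names, self.residue_seq,
                               self.residue_chain)
        ]

    def chains(self) -> list[str]:
        seen = []
        for c in self.residue_chain:
            if c not in seen:
                seen.append(c)
        return seen

    def ca_coords(self) -> tuple[np.ndarray, list[int]]:
        """Cα coordinates and the residue index of each, in residue order."""
        pts, owners = [], []
        for r in range(self.n_residues):
            sel = np.flatnonzero(self.residue_index == r)
            for i in sel:
                if self.atom_names[i] == "CA" and not self.is_solvent[i]:
                    pts.append(self.coords[i])
                    owners.append(r)
                    break
        return np.array(pts, dtype=float).reshape(-1, 3), owners


@dataclass
class DihedralTable:
    """Backbone φ/ψ angles in degrees; NaN where undefined (chain termini
    or missing backbone atoms)."""

    residue_labels: list[str]
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        for a in (self.phi, self.psi):
            ok = a[np.isfinite(a)]
            if np.any(ok <= -180.0) or np.any(ok > 180.0):
                raise ValueError("dihedral out of (-180, 180]")


def _infer_element(raw_element: str, atom_name: str) -> str:
    el = raw_element.strip()
    if el:
        return el.capitalize()
    name = "".join(ch for ch in atom_name if ch.isalpha())
    if len(name) >= 2 and name[:2].capitalize() in _TWO_LETTER_ELEMENTS:
        return name[:2].capitalize()
    return name[:1].upper() if name else "X"


def read_structure(pdb_text: str) -> MolecularStructure:
    """Parse fixed-column PDB text (ATOM/HETATM records).

    The first alternate location of each atom is kept; insertion codes are
    appended to the residue sequence key; waters and ions are retained but
    flagged via ``is_solvent``.

    Raises
    ------
    ValueError
        If no ATOM/HETATM record is present, or a coordinate field fails
        to parse (the message names the offending line number).
    """
    elements, coords, names = [], [], []
    res_index, res_names, res_seq, res_chain = [], [], [], []
    solvent = []
    res_key_to_idx: dict[tuple, int] = {}
    seen_altloc: dict[tuple, str] = {}

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        line = line.ljust(80)
        atom_name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        seq = line[22:26].strip()
        icode = line[26].strip()
        if altloc != " ":
            akey = (chain, seq, icode, atom_name)
            if akey in seen_altloc and seen_altloc[akey] != altloc:
                continue  # keep first altloc only
            seen_altloc[akey] = altloc
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError as exc:
            raise ValueError(
                f"unparseable coordinate field on line {lineno}") from exc
        rkey = (chain, seq, icode, resname)
        if rkey not in res_key_to_idx:
            res_key_to_idx[rkey] = len(res_names)
            res_names.append(resname)
            res_seq.append(seq + icode)
            res_chain.append(chain)
        elements.append(_infer_element(line[76:78], atom_name))
        coords.append(xyz)
        names.append(atom_name)
        res_index.append(res_key_to_idx[rkey])
        solvent.append(rec == "HETATM" and resname in _SOLVENT_NAMES
                       or resname in _SOLVENT_NAMES)

    if not elements:
        raise ValueError("no atoms: text contains no ATOM/HETATM records")

    return MolecularStructure(
        elements=elements,
        coords=np.array(coords),
        atom_names=names,
        residue_index=np.array(res_index),
        residue_names=res_names,
        residue_seq=res_seq,
        residue_chain=res_chain,
        is_solvent=np.array(solvent, dtype=bool),
    )


def write_pdb(structure: MolecularStructure) -> str:
    """Serialize a structure to fixed-column PDB text."""
    lines = []
    for i in range(structure.n_atoms):
        r = structure.residue_index[i]
        seq = structure.residue_seq[r]
        icode = " "
        if seq and not seq[-1].isdigit():
            seq, icode = seq[:-1], seq[-1]
        name = structure.atom_names[i]
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {i + 1:>5d} {name_field} {structure.residue_names[r]:>3s}"
            f" {structure.residue_chain[r][:1]}{int(seq):>4d}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{structure.elements[i]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def backbone_dihedrals(structure: MolecularStructure) -> DihedralTable:
    """φ/ψ backbone dihedrals per residue.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1).
    Angles at chain termini, or where a backbone atom is missing, are NaN.
    """
    backbone: list[dict[str, np.ndarray]] = []
    for r in range(structure.n_residues):
        sel = np.flatnonzero(structure.residue_index == r)
        d = {}
        for i in sel:
            nm = structure.atom_names[i]
            if nm in ("N", "CA", "C") and nm not in d:
                d[nm] = structure.coords[i]
        backbone.append(d)

    n = structure.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    chain = structure.residue_chain
    for i in range(n):
        bi = backbone[i]
        if not all(k in bi for k in ("N", "CA", "C")):
            if not structure.is_solvent[
                    np.flatnonzero(structure.residue_index == i)[0]]:
                logger.warning("residue %s missing backbone atoms; "
                               "dihedrals undefined",
                               structure.residue_labels()[i])
            continue
        if i > 0 and chain[i - 1] == chain[i] and "C" in backbone[i - 1]:
            phi[i] = dihedral_angle(backbone[i - 1]["C"], bi["N"],
                                    bi["CA"], bi["C"])
        if i + 1 < n and chain[i + 1] == chain[i] and "N" in backbone[i + 1]:
            psi[i] = dihedral_angle(bi["N"], bi["CA"], bi["C"],
                                    backbone[i + 1]["N"])
    return DihedralTable(structure.residue_labels(), phi, psi)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally superpose ``mobile`` onto ``target`` (both (n,3)).

    Centers both sets, finds the proper rotation from the SVD of the
    cross-covariance (determinant-corrected), and returns the transformed
    mobile coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - mc, target - tc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return P @ R.T + tc


def _ca_or_raise(s: MolecularStructure) -> np.ndarray:
    pts, _ = s.ca_coords()
    return pts


def rmsd_ca(frame: MolecularStructure,
            reference: MolecularStructure) -> float:
    """Optimal-superposition RMSD (Å) over Cα atoms."""
    a = _ca_or_raise(frame)
    b = _ca_or_raise(reference)
    if len(a) != len(b):
        raise ValueError(f"Cα count mismatch: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValueError("need at least 3 Cα atoms")
    moved = kabsch_superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


def rmsf_ca(frames: list[MolecularStructure],
            iterate: bool = False,
            max_iter: int = 20,
            tol: float = 1e-8) -> np.ndarray:
    """Per-residue Cα root-mean-square fluctuation (Å).

    Frames are superposed onto their Cα mean structure (one pass by
    default; ``iterate=True`` repeats superposition/mean until the mean
    converges), then RMSF(j) is the RMS displacement of Cα(j) from its
    mean position.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    cas = []
    owners0 = None
    for f in frames:
        pts, owners = f.ca_coords()
        if owners0 is None:
            owners0 = owners
        elif owners != owners0 or len(pts) != len(cas[0]):
            raise ValueError("inconsistent residue sets across frames")
        cas.append(pts)
    X = np.array([kabsch_superpose(p, cas[0]) for p in cas])
    n_pass = max_iter if iterate else 1
    for _ in range(n_pass):
        mean = X.mean(axis=0)
        Xn = np.array([kabsch_superpose(p, mean) for p in X])
        shift = np.max(np.abs(Xn - X))
        X = Xn
        if iterate and shift < tol:
            break
    mean = X.mean(axis=0)
    return np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))


def _heavy_atoms_by_residue(s: MolecularStructure):
    """Indices of non-hydrogen, non-solvent atoms grouped per residue."""
    groups = [[] for _ in range(s.n_residues)]
    for i in range(s.n_atoms):
        if s.elements[i] == "H" or s.is_solvent[i]:
            continue
        groups[s.residue_index[i]].append(i)
    return groups


def native_contacts_q(frame: MolecularStructure,
                      native: MolecularStructure,
                      cutoff: float = 4.5,
                      min_separation: int = 3,
                      tolerance: float = 1.2) -> float:
    """Fraction of native contacts Q ∈ [0, 1].

    The native contact set is every residue pair (i, j) with sequence
    separation |i−j| ≥ ``min_separation`` whose minimum heavy-atom
    distance in the native structure is below ``cutoff`` Å.  A contact is
    preserved in ``frame`` when that minimum distance stays below
    ``tolerance`` × its native value.
    """
    if frame.n_residues != native.n_residues:
        raise ValueError("residue set mismatch between frame and native")
    gn = _heavy_atoms_by_residue(native)
    gf = _heavy_atoms_by_residue(frame)

    def min_dist(s, gi, gj):
        ci = s.coords[gi][:, None, :]
        cj = s.coords[gj][None, :, :]
        return float(np.sqrt(((ci - cj) ** 2).sum(-1)).min())

    contacts = []
    n = native.n_residues
    for i in range(n):
        if not gn[i]:
            continue
        for j in range(i + min_separation, n):
            if not gn[j]:
                continue
            d = min_dist(native, gn[i], gn[j])
            if d < cutoff:
                contacts.append((i, j, d))
    if not contacts:
        raise ValueError("degenerate native: no native contacts")
    kept = sum(
        1 for i, j, d0 in contacts
        if gf[i] and gf[j] and min_dist(frame, gf[i], gf[j]) < tolerance * d0
    )
    return kept / len(contacts)
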