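"""Parsers for electronic-structure single-point outputs.

Three dialects are supported and normalized into one in-memory
representation, :class:`ElectronicStructure`:

* **Molden** files ([Atoms], [GTO], [MO] sections) — MO energies are
  converted from hartree to eV and the AO→atom map is derived from the
  basis listing;
* a subset of the **MOPAC aux** keyword format (``ATOM_EL``, ``ATOM_X``,
  ``AO_ATOMINDEX``, ``EIGENVALUES``, ``MOLECULAR_ORBITAL_OCCUPANCIES``,
  ``EIGENVECTORS``) — energies already in eV, overlap treated as the
  identity (the zero-differential-overlap convention of NDDO methods);
* an **internal JSON** schema, the lossless container used by the
  synthetic generator and tests.

All parsed systems satisfy the :class:`ElectronicStructure` invariants or
raise on load; a silently inconsistent object is never returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import HARTREE_TO_EV, OCCUPATION_THRESHOLD
from .structures import MolecularStructure

__all__ = [
    "ElectronicStructure",
    "read_molden",
    "read_mopac_aux",
    "read_internal_json",
    "write_internal_json",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

# AO counts per Molden shell label (cartesian / spherical)
_SHELL_AO_CART = {"s": 1, "p": 3, "sp": 4, "d": 6, "f": 10, "g": 15}
_SHELL_AO_SPH = {"s": 1, "p": 3, "sp": 4, "d": 5, "f": 7, "g": 9}


@dataclass
class ElectronicStructure:
    """Molecular-orbital data for one frame.

    Energies are stored in eV, ascending within the occupied block and
    within the virtual block.  ``coefficients`` is AO × MO.  ``overlap``
    is the AO overlap matrix, or ``None`` for zero-differential-overlap
    sources, in which case Mulliken condensation degrades to the
    diagonal form.
    """

    mo_energies: np.ndarray           # (n_mo,) eV
    occupations: np.ndarray           # (n_mo,) electrons
    coefficients: np.ndarray          # (n_ao, n_mo)
    ao_atom_map: np.ndarray           # (n_ao,) atom index per AO
    n_electrons: int
    overlap: np.ndarray | None = None
    source_unit: str = "eV"
    occupation_threshold: float = field(default=OCCUPATION_THRESHOLD)

    def __post_init__(self):
        self.mo_energies = np.asarray(self.mo_energies, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.ao_atom_map = np.asarray(self.ao_atom_map, dtype=int)
        n_ao, n_mo = self.coefficients.shape
        if self.mo_energies.shape != (n_mo,):
            raise ValueError("MO energy count inconsistent with coefficients")
        if self.occupations.shape != (n_mo,):
            raise ValueError("occupation count inconsistent with MO count")
        if self.ao_atom_map.shape != (n_ao,):
            raise ValueError("AO→atom map length inconsistent with AO count")
        if np.any(self.occupations < 0):
            raise ValueError("negative occupation")
        if abs(self.occupations.sum() - self.n_electrons) > 1e-6:
            raise ValueError(
                f"occupations sum {self.occupations.sum():.8f} != "
                f"electron count {self.n_electrons}")
        occ = self.occupations > self.occupation_threshold
        if not occ.any():
            raise ValueError("no occupied MO")
        for block in (self.mo_energies[occ], self.mo_energies[~occ]):
            if block.size > 1 and np.any(np.diff(block) < -1e-8):
                raise ValueError("MO energies not ascending within block")
        if self.overlap is not None:
            self.overlap = np.asarray(self.overlap, dtype=float)
            if self.overlap.shape != (n_ao, n_ao):
                raise ValueError("overlap shape mismatch")
            if not np.allclose(self.overlap, self.overlap.T, atol=1e-10):
                raise ValueError("overlap not symmetric")

    @property
    def n_ao(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_mo(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_atoms(self) -> int:
        return int(self.ao_atom_map.max()) + 1

    @property
    def homo_index(self) -> int:
        occ = np.flatnonzero(self.occupations > self.occupation_threshold)
        return int(occ[np.argmax(self.mo_energies[occ])])

    @property
    def lumo_index(self) -> int:
        vir = np.flatnonzero(self.occupations <= self.occupation_threshold)
        if vir.size == 0:
            raise ValueError("no LUMO: all MOs occupied")
        return int(vir[np.argmin(self.mo_energies[vir])])

    @property
    def e_homo(self) -> float:
        return float(self.mo_energies[self.homo_index])

    @property
    def e_lumo(self) -> float:
        return float(self.mo_energies[self.lumo_index])


def _sort_by_energy(energies, occupations, coefficients):
    """Stable sort of MOs: occupied block first, each block ascending."""
    energies = np.asarray(energies, dtype=float)
    occupations = np.asarray(occupations, dtype=float)
    occ = occupations > OCCUPATION_THRESHOLD
    order = np.concatenate([
        np.flatnonzero(occ)[np.argsort(energies[occ], kind="stable")],
        np.flatnonzero(~occ)[np.argsort(energies[~occ], kind="stable")],
    ])
    return energies[order], occupations[order], coefficients[:, order]


# ---------------------------------------------------------------------------
# Molden
# ---------------------------------------------------------------------------

def _molden_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("["):
            name = stripped[1:stripped.index("]")].lower()
            rest = stripped[stripped.index("]") + 1:].strip()
            sections[name] = [rest] if rest else []
            current = name
        elif current is not None:
            sections[current].append(line)
    return sections


def read_molden(text: str) -> tuple[MolecularStructure, ElectronicStructure]:
    """Parse Molden-format text into structure + electronic structure.

    Energies (hartree in standard Molden) are converted to eV; AO→atom
    mapping comes from counting basis functions per atom in the [GTO]
    section; coordinates flagged AU are converted to Å.
    """
    sec = _molden_sections(text)
    if "atoms" not in sec:
        raise ValueError("Molden: missing [Atoms] section")
    if "mo" not in sec:
        raise ValueError("Molden: missing [MO] section")

    unit_flag = (sec["atoms"][0].split()[0].lower()
                 if sec["atoms"] and sec["atoms"][0].strip() else "angs")
    to_ang = (1.0 / 1.8897261254578281) if unit_flag in ("au", "bohr") else 1.0
    elements, coords = [], []
    for line in sec["atoms"]:
        parts = line.split()
        if len(parts) >= 6 and _is_atom_line(line):
            elements.append(parts[0].capitalize())
            coords.append([float(p) * to_ang for p in parts[3:6]])
    if not elements:
        raise ValueError("Molden: no atoms parsed from [Atoms]")

    spherical_d = "5d" in sec or "5d7f" in sec or "5d10f" in sec
    spherical_f = "7f" in sec or "5d7f" in sec
    shell_counts = dict(_SHELL_AO_CART)
    if spherical_d:
        shell_counts["d"] = _SHELL_AO_SPH["d"]
    if spherical_f:
        shell_counts["f"] = _SHELL_AO_SPH["f"]

    ao_atom: list[int] = []
    if "gto" in sec:
        atom_idx = None
        lines = iter(sec["gto"])
        for line in lines:
            parts = line.split()
            if not parts:
                atom_idx = None
                continue
            if atom_idx is None:
                atom_idx = int(parts[0]) - 1
                continue
            label = parts[0].lower()
            if label in shell_counts:
                n_prim = int(parts[1])
                for _ in range(n_prim):
                    next(lines)
                ao_atom.extend([atom_idx] * shell_counts[label])
            else:
                raise ValueError(f"Molden: unknown shell label {label!r}")
    elif "sto" in sec:
        for line in sec["sto"]:
            parts = line.split()
            if parts:
                ao_atom.append(int(parts[0]) - 1)
    else:
        raise ValueError("Molden: missing [GTO]/[STO] basis section")

    energies, occs, cols = [], [], []
    current: list[float] | None = None
    for line in sec["mo"]:
        stripped = line.strip()
        if not stripped:
            continue
        low = stripped.lower()
        if low.startswith("ene="):
            if current is not None:
                cols.append(current)
            energies.append(float(stripped.split("=")[1]))
            current = []
        elif low.startswith("occup="):
            occs.append(float(stripped.split("=")[1]))
        elif low.startswith(("sym=", "spin=")):
            continue
        else:
            parts = stripped.split()
            if current is None or len(parts) != 2:
                raise ValueError("Molden: malformed [MO] section")
            current.append(float(parts[1]))
    if current is not None:
        cols.append(current)
    if not cols:
        raise ValueError("Molden: empty [MO] section")
    if len(energies) != len(cols) or len(occs) != len(cols):
        raise ValueError("Molden: truncated [MO] section")
    n_ao = len(ao_atom)
    for c in cols:
        if len(c) != n_ao:
            raise ValueError(
                f"Molden: [MO] coefficient count {len(c)} inconsistent "
                f"with AO count {n_ao}")

    energies_ev = np.array(energies) * HARTREE_TO_EV
    C = np.array(cols).T  # AO × MO
    occ_arr = np.array(occs)
    e, o, C = _sort_by_energy(energies_ev, occ_arr, C)
    n_elec = int(round(o.sum()))
    structure = MolecularStructure(
        elements=elements,
        coords=np.array(coords),
        atom_names=[f"{el}{i+1}" for i, el in enumerate(elements)],
        residue_index=np.arange(len(elements)),
        residue_names=["UNK"] * len(elements),
        residue_seq=[str(i + 1) for i in range(len(elements))],
        residue_chain=["A"] * len(elements),
    )
    es = ElectronicStructure(
        mo_energies=e, occupations=o, coefficients=C,
        ao_atom_map=np.array(ao_atom), n_electrons=n_elec,
        overlap=None, source_unit="hartree")
    return structure, es


def _is_atom_line(line: str) -> bool:
    parts = line.split()
    if len(parts) < 6:
        return False
    try:
        int(parts[1]); int(parts[2])
        [float(p) for p in parts[3:6]]
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# MOPAC aux
# ---------------------------------------------------------------------------

def _aux_blocks(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    key = None
    for line in text.splitlines():
        if "=" in line and line.lstrip()[:1].isalpha():
            head, _, rest = line.partition("=")
            key = head.split("[")[0].split(":")[0].strip().upper()
            blocks[key] = [rest.strip()] if rest.strip() else []
        elif key is not None:
            blocks[key].append(line.strip())
    return blocks


def _aux_values(blocks, key, cast=float):
    out = []
    for line in blocks[key]:
        out.extend(cast(tok) for tok in line.replace(",", " ").split() if tok)
    return out


def read_mopac_aux(text: str) -> tuple[MolecularStructure,
                                       ElectronicStructure]:
    """Parse a MOPAC aux-style file (subset of keywords).

    Energies are native eV.  The overlap is taken as the identity, per
    the NDDO zero-differential-overlap convention, so condensation uses
    the diagonal form.  If the occupations block is absent, a closed
    shell is assumed and the lowest N/2 MOs are filled with 2 electrons;
    an odd electron count is rejected.
    """
    blocks = _aux_blocks(text)
    for req in ("ATOM_EL", "ATOM_X", "EIGENVALUES", "EIGENVECTORS"):
        if req not in blocks:
            raise ValueError(f"MOPAC aux: missing {req} block")
    elements = [e.capitalize() for e in _aux_values(blocks, "ATOM_EL", str)]
    xyz = _aux_values(blocks, "ATOM_X")
    if len(xyz) != 3 * len(elements):
        raise ValueError("MOPAC aux: coordinate count mismatch")
    coords = np.array(xyz).reshape(-1, 3)

    energies = np.array(_aux_values(blocks, "EIGENVALUES"))
    n_mo = len(energies)
    vec = _aux_values(blocks, "EIGENVECTORS")
    if len(vec) % n_mo != 0:
        raise ValueError("MOPAC aux: eigenvector count inconsistent "
                         "with MO count")
    n_ao = len(vec) // n_mo
    # aux stores eigenvectors MO-major
    C = np.array(vec).reshape(n_mo, n_ao).T

    if "AO_ATOMINDEX" in blocks:
        ao_atom = np.array(
            _aux_values(blocks, "AO_ATOMINDEX", int)) - 1
        if len(ao_atom) != n_ao:
            raise ValueError("MOPAC aux: AO_ATOMINDEX length mismatch")
    elif n_ao == len(elements):
        ao_atom = np.arange(n_ao)
    else:
        raise ValueError("MOPAC aux: missing AO_ATOMINDEX block")

    if "MOLECULAR_ORBITAL_OCCUPANCIES" in blocks:
        occs = np.array(_aux_values(blocks, "MOLECULAR_ORBITAL_OCCUPANCIES"))
        if len(occs) != n_mo:
            raise ValueError("MOPAC aux: occupancy count mismatch")
        n_elec = int(round(occs.sum()))
    else:
        if "NUM_ELECTRONS" in blocks:
            n_elec = int(_aux_values(blocks, "NUM_ELECTRONS", float)[0])
        else:
            raise ValueError("MOPAC aux: no occupancies and no NUM_ELECTRONS")
        if n_elec % 2 != 0:
            raise ValueError("open shell unsupported: odd electron count "
                             "with closed-shell aufbau fill")
        occs = np.zeros(n_mo)
        occs[np.argsort(energies, kind="stable")[: n_elec // 2]] = 2.0

    e, o, C = _sort_by_energy(energies, occs, C)
    structure = MolecularStructure(
        elements=elements,
        coords=coords,
        atom_names=[f"{el}{i+1}" for i, el in enumerate(elements)],
        residue_index=np.arange(len(elements)),
        residue_names=["UNK"] * len(elements),
        residue_seq=[str(i + 1) for i in range(len(elements))],
        residue_chain=["A"] * len(elements),
    )
    es = ElectronicStructure(
        mo_energies=e, occupations=o, coefficients=C,
        ao_atom_map=ao_atom, n_electrons=n_elec,
        overlap=None, source_unit="eV")
    return structure, es


# ---------------------------------------------------------------------------
# Internal JSON
# ---------------------------------------------------------------------------

def write_internal_json(structure: MolecularStructure,
                        es: ElectronicStructure) -> str:
    """Serialize to the internal JSON schema (lossless)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "atoms": [
            {
                "element": structure.elements[i],
                "name": structure.atom_names[i],
                "xyz": list(structure.coords[i]),
                "residue": {
                    "name": structure.residue_names[
                        structure.residue_index[i]],
                    "seq": structure.residue_seq[structure.residue_index[i]],
                    "chain": structure.residue_chain[
                        structure.residue_index[i]],
                },
            }
            for i in range(structure.n_atoms)
        ],
        "ao_atom_map": es.ao_atom_map.tolist(),
        "mo_energies_ev": es.mo_energies.tolist(),
        "occupations": es.occupations.tolist(),
        "coefficients": es.coefficients.tolist(),
        "n_electrons": es.n_electrons,
    }
    if es.overlap is not None:
        doc["overlap"] = es.overlap.tolist()
    return json.dumps(doc)


def read_internal_json(text: str) -> tuple[MolecularStructure,
                                           ElectronicStructure]:
    """Read the internal JSON schema back into domain objects."""
    doc = json.loads(text)
    version = doc.get("schema_version")
    if version is None:
        raise ValueError("internal JSON: missing schema version field")
    if str(version) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {version!r}")
    for req in ("atoms", "ao_atom_map", "mo_energies_ev", "occupations",
                "coefficients"):
        if req not in doc:
            raise ValueError(f"internal JSON: missing field {req!r}")

    atoms = doc["atoms"]
    res_keys: dict[tuple, int] = {}
    res_names, res_seq, res_chain, res_index = [], [], [], []
    for a in atoms:
        r = a["residue"]
        k = (r["chain"], r["seq"], r["name"])
        if k not in res_keys:
            res_keys[k] = len(res_names)
            res_names.append(r["name"])
            res_seq.append(str(r["seq"]))
            res_chain.append(r["chain"])
        res_index.append(res_keys[k])
    structure = MolecularStructure(
        elements=[a["element"] for a in atoms],
        coords=np.array([a["xyz"] for a in atoms]),
        atom_names=[a.get("name", f"X{i+1}") for i, a in enumerate(atoms)],
        residue_index=np.array(res_index),
        residue_names=res_names,
        residue_seq=res_seq,
        residue_chain=res_chain,
    )
    es = ElectronicStructure(
        mo_energies=np.array(doc["mo_energies_ev"]),
        occupations=np.array(doc["occupations"]),
        coefficients=np.array(doc["coefficients"]),
        ao_atom_map=np.array(doc["ao_atom_map"]),
        n_electrons=int(doc["n_electrons"]),
        overlap=(np.array(doc["overlap"]) if "overlap" in doc else None),
        source_unit="eV",
    )
    return structure, es
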