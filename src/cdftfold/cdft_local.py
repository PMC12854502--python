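"""Atom-condensed local reactivity descriptors and residue condensation.

Populations, Fukui functions (frozen-orbital, energy-weighted and
finite-difference), local softness, and four definitions of local
hardness, all condensed per atom and optionally summed per residue.

Population scheme
-----------------
Mulliken: with the AO overlap matrix S, ρ_A = Σ_{μ∈A} (P·S)_{μμ} where
P = C·diag(occ)·Cᵀ; without an overlap (zero-differential-overlap
sources) the diagonal form ρ_A = Σ_{μ∈A} P_{μμ} is used.  A Löwdin
variant (symmetric orthogonalization, ρ_A = Σ_{μ∈A} (S^½·P·S^½)_{μμ})
is available via ``scheme="lowdin"``.

Local hardness
--------------
Four condensed working definitions:

* ``hardness_tfd`` — Thomas–Fermi–Dirac electron–electron potential,
  η_A = (1/2N) Σ_{B≠A} ρ_B / r_AB (atomic units, distances in bohr);
* ``hardness_fukui_potential`` — the Fukui potential,
  η_A = Σ_{B≠A} f_B / r_AB;
* ``hardness_lcp`` — local-chemical-potential form,
  η_A = (ρ_HOMO,A − ρ_A/N)·μ/(2N) + (ρ_A/N)·η, which integrates to the
  global hardness exactly;
* ``hardness_fw`` — Fukui-weighted, η_A = IP·f⁻_A − EA·f⁺_A, which also
  sums to η = IP − EA for normalized Fukui inputs.

The TFD and Fukui-potential forms do not integrate to the global
quantity; downstream analysis z-normalizes, so their absolute scale is
not load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import sqrtm

from .constants import ANGSTROM_TO_BOHR, MIN_SEPARATION_BOHR
from .cdft_global import GlobalDescriptors
from .qm_io import ElectronicStructure
from .structures import MolecularStructure

__all__ = [
    "CondensedField",
    "ResidueField",
    "DESCRIPTOR_NAMES",
    "mulliken_populations",
    "orbital_density",
    "fukui_foa",
    "fukui_ew",
    "fukui_finite_difference",
    "fukui_composites",
    "local_softness",
    "local_hardness_tfd",
    "fukui_potential",
    "local_hardness_lcp",
    "local_hardness_fw",
    "condense_to_residues",
]

#: Controlled vocabulary of condensed descriptor names.  The softness
#: variants carry the traditional attack-susceptibility aliases:
#: EAS (electrophilic) = S·f⁻, NAS (nucleophilic) = S·f⁺,
#: RAS (radical) = S·f⁰.
DESCRIPTOR_NAMES = (
    "rho", "f_minus", "f_plus", "f_zero", "f_dual",
    "softness_minus", "softness_plus", "softness_zero",
    "hardness_tfd", "hardness_fukui_potential", "hardness_lcp",
    "hardness_fw",
)


@dataclass
class CondensedField:
    """One named local descriptor's per-atom values for one frame."""

    name: str
    values: np.ndarray
    unit: str = "au"
    frame_id: str | int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("condensed field must be one value per atom")


@dataclass
class ResidueField:
    """Per-residue sums of a condensed field."""

    name: str
    values: np.ndarray
    residue_labels: list[str]
    residue_names: list[str]
    frame_id: str | int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.residue_labels):
            raise ValueError("one value per residue required")


def _density_matrix(es: ElectronicStructure) -> np.ndarray:
    return (es.coefficients * es.occupations) @ es.coefficients.T


def _condense_diag(diag: np.ndarray, ao_atom_map: np.ndarray) -> np.ndarray:
    n_atoms = int(ao_atom_map.max()) + 1
    return np.bincount(ao_atom_map, weights=diag, minlength=n_atoms)


def mulliken_populations(es: ElectronicStructure,
                         scheme: str = "mulliken",
                         frame_id=None) -> CondensedField:
    """Per-atom electron populations, Σ_A ρ_A = N.

    ``scheme`` is ``"mulliken"`` (default; degrades to the diagonal form
    when no overlap is present) or ``"lowdin"``.
    """
    P = _density_matrix(es)
    if scheme not in ("mulliken", "lowdin"):
        raise ValueError(f"unknown population scheme {scheme!r}")
    if es.overlap is None:
        diag = np.diag(P).copy()
    elif scheme == "mulliken":
        diag = np.einsum("ij,ji->i", P, es.overlap)
    else:
        s_half = np.real(sqrtm(es.overlap))
        diag = np.diag(s_half @ P @ s_half).copy()
    return CondensedField("rho", _condense_diag(diag, es.ao_atom_map),
                          unit="e", frame_id=frame_id)


def orbital_density(es: ElectronicStructure, mo_index: int,
                    frame_id=None) -> CondensedField:
    """Per-atom weight of |ψ_i|², condensed like the populations and
    normalized to sum 1."""
    if not 0 <= mo_index < es.n_mo:
        raise ValueError(f"MO index {mo_index} out of range")
    c = es.coefficients[:, mo_index]
    if es.overlap is None:
        diag = c * c
    else:
        diag = c * (es.overlap @ c)
    per_atom = _condense_diag(diag, es.ao_atom_map)
    total = per_atom.sum()
    if abs(total) < 1e-12:
        raise ValueError("degenerate orbital density (zero norm)")
    return CondensedField("orbital_density", per_atom / total,
                          unit="1", frame_id=frame_id)


def fukui_foa(es: ElectronicStructure,
              frame_id=None) -> tuple[CondensedField, CondensedField]:
    """Frozen-orbital Fukui functions: f⁻ = |HOMO|², f⁺ = |LUMO|²
    (condensed, each summing to 1)."""
    f_minus = orbital_density(es, es.homo_index, frame_id)
    f_plus = orbital_density(es, es.lumo_index, frame_id)
    f_minus.name, f_plus.name = "f_minus", "f_plus"
    return f_minus, f_plus


def fukui_ew(es: ElectronicStructure, window: float = 1.0,
             frame_id=None) -> tuple[CondensedField, CondensedField]:
    """Energy-weighted Fukui functions for (near-)degenerate systems.

    Occupied MOs within ``window`` eV of the HOMO (virtuals within the
    window of the LUMO) contribute their condensed densities weighted by
    exp(−|E_i − E_ref|), with the energy difference in eV; the result is
    renormalized to sum 1 so downstream conservation identities hold.
    With ``window=0`` only exactly degenerate frontier orbitals enter
    and the non-degenerate case reduces to the frozen-orbital form.
    """
    if window < 0:
        raise ValueError("window must be non-negative")

    def weighted(ref_energy: float, indices: np.ndarray) -> np.ndarray:
        sel = indices[np.abs(es.mo_energies[indices] - ref_energy)
                      <= window + 1e-12]
        acc = np.zeros(es.n_atoms)
        for i in sel:
            w = np.exp(-abs(es.mo_energies[i] - ref_energy))
            acc += w * orbital_density(es, int(i)).values
        return acc / acc.sum()

    occ = np.flatnonzero(es.occupations > es.occupation_threshold)
    vir = np.flatnonzero(es.occupations <= es.occupation_threshold)
    if vir.size == 0:
        raise ValueError("no LUMO")
    f_minus = CondensedField("f_minus", weighted(es.e_homo, occ),
                             unit="1", frame_id=frame_id)
    f_plus = CondensedField("f_plus", weighted(es.e_lumo, vir),
                            unit="1", frame_id=frame_id)
    return f_minus, f_plus


def fukui_finite_difference(
        rho_n: CondensedField,
        rho_n_minus_1: CondensedField,
        rho_n_plus_1: CondensedField,
        frame_id=None) -> tuple[CondensedField, CondensedField]:
    """Finite-difference Fukui functions from N, N−1, N+1 populations:
    f⁻ = ρ_N − ρ_{N−1}, f⁺ = ρ_{N+1} − ρ_N (element-wise per atom)."""
    n = len(rho_n.values)
    if len(rho_n_minus_1.values) != n or len(rho_n_plus_1.values) != n:
        raise ValueError("mismatched atom sets across population fields")
    f_minus = CondensedField(
        "f_minus", rho_n.values - rho_n_minus_1.values, "1", frame_id)
    f_plus = CondensedField(
        "f_plus", rho_n_plus_1.values - rho_n.values, "1", frame_id)
    return f_minus, f_plus


def fukui_composites(f_minus: CondensedField, f_plus: CondensedField
                     ) -> tuple[CondensedField, CondensedField]:
    """Radical and dual Fukui functions: f⁰ = (f⁻+f⁺)/2, f± = f⁺−f⁻."""
    if len(f_minus.values) != len(f_plus.values):
        raise ValueError("mismatched atom sets")
    f_zero = CondensedField(
        "f_zero", 0.5 * (f_minus.values + f_plus.values), "1",
        f_minus.frame_id)
    f_dual = CondensedField(
        "f_dual", f_plus.values - f_minus.values, "1", f_minus.frame_id)
    return f_zero, f_dual


def local_softness(f: CondensedField, softness: float) -> CondensedField:
    """Local softness s_A = S·f_A; sums to the global softness S."""
    tag = {"f_minus": "softness_minus", "f_plus": "softness_plus",
           "f_zero": "softness_zero"}.get(f.name, f"softness({f.name})")
    return CondensedField(tag, softness * f.values, "1/eV", f.frame_id)


def _pair_inverse_distances(structure: MolecularStructure) -> np.ndarray:
    """Inverse interatomic distance matrix in 1/bohr, zero diagonal."""
    xyz = structure.coords * ANGSTROM_TO_BOHR
    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    n = len(xyz)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < MIN_SEPARATION_BOHR):
        raise ValueError("overlapping centers: interatomic distance below "
                         f"{MIN_SEPARATION_BOHR} bohr")
    inv = np.zeros_like(r)
    inv[off] = 1.0 / r[off]
    return inv


def local_hardness_tfd(structure: MolecularStructure, rho: CondensedField,
                       n_electrons: int, frame_id=None) -> CondensedField:
    """TFD local hardness η_A = (1/2N)·Σ_{B≠A} ρ_B / r_AB (a.u.).

    The self term is excluded: the point-charge condensation of the
    1/|r−r′| kernel diverges at zero distance.
    """
    if structure.n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    if n_electrons <= 0:
        raise ValueError("electron count must be positive")
    if len(rho.values) != structure.n_atoms:
        raise ValueError("population field does not match structure")
    inv = _pair_inverse_distances(structure)
    vals = (inv @ rho.values) / (2.0 * n_electrons)
    return CondensedField("hardness_tfd", vals, "au", frame_id)


def fukui_potential(structure: MolecularStructure, f: CondensedField,
                    frame_id=None) -> CondensedField:
    """Fukui potential η_A = Σ_{B≠A} f_B / r_AB (a.u., self-excluded).

    Accepts any Fukui variant (f⁻ by convention; f⁺ or f⁰ give the
    generalized forms)."""
    if structure.n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    if len(f.values) != structure.n_atoms:
        raise ValueError("Fukui field does not match structure")
    inv = _pair_inverse_distances(structure)
    return CondensedField("hardness_fukui_potential", inv @ f.values,
                          "au", frame_id)


def local_hardness_lcp(es: ElectronicStructure, rho: CondensedField,
                       g: GlobalDescriptors, frame_id=None) -> CondensedField:
    """Local-chemical-potential hardness.

    η_A = (ρ_HOMO,A − ρ_A/N)·μ/(2N) + (ρ_A/N)·η, with ρ_HOMO the
    condensed HOMO density (Σ = 1).  The first term telescopes to zero
    over atoms, so Σ_A η_A = η exactly — the global integration
    constraint this definition is built to satisfy.
    """
    rho_homo = orbital_density(es, es.homo_index).values
    n = es.n_electrons
    frac = rho.values / n
    vals = (rho_homo - frac) * g.mu / (2.0 * n) + frac * g.eta
    return CondensedField("hardness_lcp", vals, "eV", frame_id)


def local_hardness_fw(f_minus: CondensedField, f_plus: CondensedField,
                      ip: float, ea: float, frame_id=None) -> CondensedField:
    """Fukui-weighted local hardness η_A = IP·f⁻_A − EA·f⁺_A.

    For normalized Fukui inputs Σ_A η_A = IP − EA = η.
    """
    if len(f_minus.values) != len(f_plus.values):
        raise ValueError("mismatched atom sets")
    vals = ip * f_minus.values - ea * f_plus.values
    return CondensedField("hardness_fw", vals, "eV", f_minus.frame_id
                          if frame_id is None else frame_id)


def condense_to_residues(field: CondensedField,
                         structure: MolecularStructure) -> ResidueField:
    """Sum per-atom values over each residue's member atoms."""
    if len(field.values) != structure.n_atoms:
        raise ValueError("field does not match structure atom count")
    if np.any(structure.residue_index < 0) or \
            np.any(structure.residue_index >= structure.n_residues):
        raise ValueError("unmapped atom in residue assignment")
    sums = np.bincount(structure.residue_index, weights=field.values,
                       minlength=structure.n_residues)
    return ResidueField(field.name, sums, structure.residue_labels(),
                        list(structure.residue_names), field.frame_id)
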