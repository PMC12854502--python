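"""Synthetic inputs for every pipeline stage.

Three generator families, all pure functions of their spec (seed
included):

* valid electronic structures — random orthonormal MO sets with
  controllable gaps/degeneracies and optional random symmetric-positive
  AO overlap, plus exactly solvable tight-binding chains whose closed
  forms serve as analytic oracles;
* toy protein structures and folding trajectories — per-residue
  descriptor series whose fluctuation amplitude drops at a planted
  change-point frame, with matching Cα geometry interpolating an
  extended chain into a compact conformation (so RMSD/Q stages see a
  consistent structural signal);
* hidden two-state Markov emission series with analytically known
  lag-τ autocorrelation (1 − 2p)^τ, the oracle for tICA.

The descriptor series uses Gaussian fluctuations around per-residue
baselines: the qualitative behaviour being emulated is an amplitude
drop at the change point, and a Gaussian is the minimal noise model
carrying an amplitude parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdft_local import ResidueField
from .qm_io import ElectronicStructure
from .structures import MolecularStructure, rmsd_ca

__all__ = [
    "SyntheticSpec",
    "make_toy_electronic_structure",
    "make_tight_binding_chain",
    "make_synthetic_trajectory",
    "make_two_state_series",
]

_RESIDUE_CYCLE = (
    "ALA", "GLY", "LEU", "SER", "VAL", "PHE", "ASP", "LYS", "THR", "GLU",
    "ILE", "ASN", "ARG", "TRP", "PRO", "GLN", "TYR", "MET", "HIS", "ASP",
)


@dataclass
class SyntheticSpec:
    """Parameters for the synthetic generators.

    Electronic-structure fields: ``n_atoms``, ``aos_per_atom``,
    ``n_electrons`` (even; default half-fills the AO space),
    ``mo_energies`` (explicit eV list, or None for a random spectrum
    with ``homo_lumo_gap``), ``overlap_mode`` ("identity" |
    "random_spd").

    Trajectory fields: ``n_frames``, ``n_residues``, ``changepoint``
    (first frame of the stabilized segment), ``sigma_pre`` /
    ``sigma_post`` (descriptor noise SD before/after), ``baselines``
    (per-residue values; default drawn N(10, 2²)).
    """

    seed: int = 0
    n_atoms: int = 6
    aos_per_atom: int = 2
    n_electrons: int | None = None
    mo_energies: list | None = None
    homo_lumo_gap: float = 4.0
    overlap_mode: str = "identity"
    degenerate_homo_atoms: tuple[int, ...] | None = None
    # trajectory parameters
    n_frames: int = 100
    n_residues: int = 20
    changepoint: int = 60
    sigma_pre: float = 1.0
    sigma_post: float = 0.1
    baselines: np.ndarray | None = None
    min_segment: int = 5

    def __post_init__(self):
        if self.sigma_post > self.sigma_pre:
            raise ValueError("sigma_post must not exceed sigma_pre")
        if not (self.min_segment < self.changepoint
                < self.n_frames - self.min_segment + 1):
            raise ValueError("change point too close to trajectory ends")
        if self.n_electrons is not None and self.n_electrons % 2 != 0:
            raise ValueError("electron count must be even (closed shell)")


def _toy_structure(n_atoms: int, rng: np.random.Generator,
                   spacing: float = 1.5) -> MolecularStructure:
    """Random jittered chain geometry, one residue per atom, min
    separation enforced."""
    coords = np.cumsum(
        spacing * (np.ones((n_atoms, 3)) * [1.0, 0.0, 0.0])
        + 0.3 * rng.standard_normal((n_atoms, 3)), axis=0)
    return MolecularStructure(
        elements=["C"] * n_atoms,
        coords=coords,
        atom_names=[f"C{i+1}" for i in range(n_atoms)],
        residue_index=np.arange(n_atoms),
        residue_names=[_RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
                       for i in range(n_atoms)],
        residue_seq=[str(i + 1) for i in range(n_atoms)],
        residue_chain=["A"] * n_atoms,
    )


def make_toy_electronic_structure(
        spec: SyntheticSpec) -> tuple[MolecularStructure,
                                      ElectronicStructure]:
    """Random valid electronic structure satisfying all invariants.

    Coefficients come from a random orthogonal matrix (QR of a seeded
    Gaussian draw).  With ``overlap_mode="random_spd"`` a random
    symmetric positive-definite overlap with unit diagonal is generated
    and the coefficients back-transformed so generalized orthonormality
    CᵀSC = I holds.  Occupations are aufbau.  With
    ``degenerate_homo_atoms`` the top two occupied MOs are made exactly
    degenerate and localized one-per-atom on the given atoms.
    """
    rng = np.random.default_rng(spec.seed)
    n_ao = spec.n_atoms * spec.aos_per_atom
    n_elec = spec.n_electrons if spec.n_electrons is not None \
        else 2 * max(1, n_ao // 2)
    if n_elec // 2 > n_ao:
        raise ValueError("more electron pairs than AOs")
    n_occ = n_elec // 2
    if n_occ < 1 or n_occ >= n_ao:
        raise ValueError("need at least one occupied and one virtual MO")

    if spec.mo_energies is not None:
        energies = np.asarray(spec.mo_energies, dtype=float)
        if len(energies) != n_ao:
            raise ValueError("explicit energy list must cover every MO")
    else:
        occ_e = np.sort(rng.uniform(-20.0, -5.0, n_occ))
        occ_e[-1] = -5.0
        vir_e = np.sort(rng.uniform(-5.0 + spec.homo_lumo_gap,
                                    -5.0 + spec.homo_lumo_gap + 10.0,
                                    n_ao - n_occ))
        vir_e[0] = -5.0 + spec.homo_lumo_gap
        energies = np.concatenate([occ_e, vir_e])

    Q, _ = np.linalg.qr(rng.standard_normal((n_ao, n_ao)))
    ao_map = np.repeat(np.arange(spec.n_atoms), spec.aos_per_atom)

    if spec.degenerate_homo_atoms is not None:
        atoms = spec.degenerate_homo_atoms
        if len(atoms) < 2:
            raise ValueError("need >= 2 atoms for a degenerate HOMO pair")
        if n_occ < len(atoms):
            raise ValueError("not enough occupied MOs to localize")
        # rebuild: localized frontier MOs on one AO of each listed atom,
        # remaining MOs orthogonal to them
        C = np.zeros((n_ao, n_ao))
        frontier_aos = [int(a) * spec.aos_per_atom for a in atoms]
        rest = [i for i in range(n_ao) if i not in frontier_aos]
        sub, _ = np.linalg.qr(
            rng.standard_normal((len(rest), len(rest))))
        for k, ao in enumerate(frontier_aos):
            C[ao, n_occ - len(atoms) + k] = 1.0
        other_cols = [j for j in range(n_ao)
                      if not n_occ - len(atoms) <= j < n_occ]
        for col, j in enumerate(other_cols):
            C[rest, j] = sub[:, col]
        Q = C
        e_h = energies[n_occ - 1]
        energies[n_occ - len(atoms):n_occ] = e_h

    overlap = None
    if spec.overlap_mode == "random_spd":
        A = rng.standard_normal((n_ao, n_ao))
        S = A @ A.T + n_ao * np.eye(n_ao)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        L = np.linalg.cholesky(S)
        C = np.linalg.solve(L.T, Q)   # CᵀSC = QᵀQ = I
        overlap = S
    elif spec.overlap_mode == "identity":
        C = Q
    else:
        raise ValueError(f"unknown overlap mode {spec.overlap_mode!r}")

    occs = np.zeros(n_ao)
    occs[:n_occ] = 2.0
    structure = _toy_structure(spec.n_atoms, rng)
    es = ElectronicStructure(
        mo_energies=energies, occupations=occs, coefficients=C,
        ao_atom_map=ao_map, n_electrons=n_elec, overlap=overlap)
    return structure, es


def make_tight_binding_chain(n_sites: int, alpha: float = 0.0,
                             beta: float = -1.0
                             ) -> tuple[MolecularStructure,
                                        ElectronicStructure]:
    """Half-filled nearest-neighbour tight-binding chain (exact).

    Eigenvalues E_k = α + 2β·cos(kπ/(n+1)) and eigenvector components
    C_jk ∝ sin(jkπ/(n+1)), k = 1..n, built from the closed form (no
    numerical diagonalization), so they can serve as an analytic oracle.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if beta >= 0:
        raise ValueError("beta must be negative (bonding convention)")
    n = n_sites
    k = np.arange(1, n + 1)
    energies = alpha + 2.0 * beta * np.cos(k * np.pi / (n + 1))
    j = np.arange(1, n + 1)
    C = np.sqrt(2.0 / (n + 1)) * np.sin(np.outer(j, k) * np.pi / (n + 1))
    order = np.argsort(energies, kind="stable")
    energies, C = energies[order], C[:, order]
    n_elec = 2 * (n // 2)
    occs = np.zeros(n)
    occs[: n // 2] = 2.0
    coords = np.zeros((n, 3))
    coords[:, 0] = 1.4 * np.arange(n)
    structure = MolecularStructure(
        elements=["C"] * n,
        coords=coords,
        atom_names=[f"C{i+1}" for i in range(n)],
        residue_index=np.arange(n),
        residue_names=[_RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
                       for i in range(n)],
        residue_seq=[str(i + 1) for i in range(n)],
        residue_chain=["A"] * n,
    )
    es = ElectronicStructure(
        mo_energies=energies, occupations=occs, coefficients=C,
        ao_atom_map=np.arange(n), n_electrons=n_elec)
    return structure, es


def _chain_conformation(n_res: int, t: float) -> np.ndarray:
    """Cα coordinates interpolating extended (t=0) → compact helix-like
    (t=1); Cα–Cα spacing stays near 3.8 Å."""
    i = np.arange(n_res)
    extended = np.stack([3.8 * i, np.zeros(n_res), np.zeros(n_res)], axis=1)
    theta = i * 100.0 * np.pi / 180.0
    compact = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i],
                       axis=1)
    return (1.0 - t) * extended + t * compact


def _trajectory_structure(n_res: int, t: float) -> MolecularStructure:
    ca = _chain_conformation(n_res, t)
    return MolecularStructure(
        elements=["C"] * n_res,
        coords=ca,
        atom_names=["CA"] * n_res,
        residue_index=np.arange(n_res),
        residue_names=[_RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
                       for i in range(n_res)],
        residue_seq=[str(i + 1) for i in range(n_res)],
        residue_chain=["A"] * n_res,
    )


def make_synthetic_trajectory(
        spec: SyntheticSpec,
        descriptor: str = "hardness_tfd"
) -> tuple[list[ResidueField], list[MolecularStructure], np.ndarray]:
    """Folding trajectory with a planted fluctuation change point.

    Frames are ordered non-native first.  Residue j's value at frame i
    is baseline_j + ε with ε ~ N(0, σ_pre²) before the change point and
    N(0, σ_post²) from the change point on.  Cα geometry interpolates
    an extended chain into a compact conformation so that the returned
    RMSD series (vs the final compact frame) is strictly minimized
    after the change point.
    """
    rng = np.random.default_rng(spec.seed)
    F, R = spec.n_frames, spec.n_residues
    cp = spec.changepoint
    baselines = (np.asarray(spec.baselines, dtype=float)
                 if spec.baselines is not None
                 else 10.0 + 2.0 * rng.standard_normal(R))
    if len(baselines) != R:
        raise ValueError("baselines length mismatch")

    sigmas = np.where(np.arange(F) < cp, spec.sigma_pre, spec.sigma_post)
    values = baselines[None, :] + sigmas[:, None] * \
        rng.standard_normal((F, R))

    # folding progress: slow compaction before the change point, compact
    # after; the final frame is exactly the compact reference
    t = np.empty(F)
    t[:cp] = 0.6 * np.arange(cp) / max(cp - 1, 1)
    t[cp:] = np.linspace(0.9, 1.0, F - cp)
    structures = [_trajectory_structure(R, ti) for ti in t]
    native = structures[-1]
    rmsd = np.array([rmsd_ca(s, native) for s in structures])

    labels = structures[0].residue_labels()
    names = list(structures[0].residue_names)
    fields = [
        ResidueField(descriptor, values[i], labels, names, frame_id=i)
        for i in range(F)
    ]
    return fields, structures, rmsd


def make_two_state_series(n_frames: int = 20000, flip_prob: float = 0.05,
                          n_features: int = 5, noise_sd: float = 0.1,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Hidden two-state Markov chain emitted into noisy features.

    The hidden state flips with probability ``flip_prob`` per step, so
    its lag-τ autocorrelation is (1 − 2·flip_prob)^τ by construction.
    Emissions are state · mean-vector + N(0, noise_sd²) per feature.
    Returns (features, hidden state ±1).
    """
    if not 0.0 < flip_prob < 0.5:
        raise ValueError("flip probability must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    flips = rng.random(n_frames) < flip_prob
    state = np.empty(n_frames)
    s = 1.0
    for i in range(n_frames):
        if flips[i]:
            s = -s
        state[i] = s
    means = rng.uniform(0.5, 1.5, n_features) * \
        np.sign(rng.standard_normal(n_features))
    X = state[:, None] * means[None, :] + \
        noise_sd * rng.standard_normal((n_frames, n_features))
    return X, state
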