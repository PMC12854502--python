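# cdftfold

Conceptual-DFT reactivity descriptors along protein folding trajectories.

`cdftfold` asks an electronic-structure question about folding: as a
protein moves from extended, non-native conformations to its native
topology, how do its chemical reactivity descriptors change?  The
package computes global and per-residue conceptual-DFT descriptors from
quantum-chemical single-point outputs for each trajectory frame, orders
the frames along a tICA folding coordinate, and classifies the
trajectory into non-native and native-like segments from the point where
per-residue hardness fluctuations stabilize.

## The descriptors

From the frontier molecular-orbital energies (frozen orbital
approximation), per frame:

| quantity | formula |
|---|---|
| ionization potential | IP = −E_HOMO |
| electron affinity | EA = −E_LUMO |
| chemical potential | μ = (E_HOMO + E_LUMO)/2 |
| hardness | η = E_LUMO − E_HOMO |
| softness | S = 1/η |
| electrophilicity | ω = μ²S/2 |
| maximal electron acceptance | nMax = −μ/η |

Locally, condensed per atom and summed per residue:

- **Fukui functions** f⁻, f⁺ (frozen-orbital: HOMO/LUMO densities;
  finite-difference: ρ_N − ρ_{N−1}, ρ_{N+1} − ρ_N), the radical and dual
  composites f⁰ = (f⁻+f⁺)/2, f± = f⁺−f⁻, and the **energy-weighted**
  variants f⁻_EW, f⁺_EW = Σ_i exp(−|E_i − E_frontier|)·|ψ_i|² over the
  frontier-adjacent orbitals, built for the near-degenerate orbital
  manifolds of biopolymers.
- **Local softness** s(r) = S·f(r) (the EAS/NAS/RAS site-susceptibility
  measures).
- **Local hardness**, four working definitions: the Thomas–Fermi–Dirac
  electron–electron potential η_A = (1/2N)·Σ_{B≠A} ρ_B/r_AB (the
  default for trajectory analysis), the Fukui potential
  Σ_{B≠A} f_B/r_AB, a local-chemical-potential form that integrates
  exactly to the global η, and the Fukui-weighted form
  IP·f⁻_A − EA·f⁺_A.

Along the trajectory, each residue's hardness is referenced to the
frame of lowest RMSD-Cα (the folded reference r):
Δη_j^i = η_j^i − η_j^r.  The mean |Δη| per frame is segmented by a
single least-squares change point; the lower-fluctuation segment is
labeled native-like.

## Worked example

Generate a synthetic 6-atom electronic structure and compute its global
descriptors:

```sh
cdftfold synth es --seed 1 --atoms 6 --out sys.json
cdftfold global sys.json --out global.csv
cat global.csv
```

```
frame,IP,EA,mu,eta,S,omega,nmax
sys,5.0,1.0,-3.0,4.0,0.25,1.125,0.75
```

HOMO at −5 eV and LUMO at −1 eV give a 4 eV gap, hence hardness
η = 4 eV, softness S = 0.25 eV⁻¹, chemical potential μ = −3 eV, and
electrophilicity ω = μ²S/2 = 1.125 eV.

Run the trajectory analysis on a synthetic folding trajectory with a
fluctuation change point planted at frame 60:

```sh
cdftfold synth traj --seed 1 --frames 100 --residues 20 \
    --changepoint 60 --out traj
cdftfold analyze --local traj/local.csv --rmsd traj/rmsd.csv \
    --descriptor hardness_tfd --out report
```

```
change point at frame index 60 (reference frame 99)
```

The classifier recovers the planted boundary exactly: frames 0–59 are
labeled non-native, frames 60–99 native-like, and the Δη reference is
the minimum-RMSD frame (99).  `report/group_averages.csv` summarizes
Δη by physicochemical residue group and region, e.g.

```
group,group_label,region,mean,sd,n_cells
1,nonpolar aliphatic,non-native,-0.100,1.044,420
1,nonpolar aliphatic,native-like,-0.041,0.171,280
```

— the fluctuation (sd) of the nonpolar-aliphatic residues drops from
1.04 to 0.17 across the boundary, the stabilization signature the
classifier keys on.

Real data enter the same way: per-frame PDB files plus Molden or
MOPAC-aux single-point outputs (`cdftfold qm convert` normalizes either
into the internal JSON schema), `cdftfold tica fit`/`sample` to order
frames along the folding coordinate, and `cdftfold struct
rmsd|rmsf|qfrac` for the structural metrics.

## Layout

- `src/cdftfold/structures.py` — PDB I/O, dihedrals, RMSD/RMSF/Q
- `src/cdftfold/qm_io.py` — Molden / MOPAC-aux / internal-JSON parsers
- `src/cdftfold/cdft_global.py`, `cdft_local.py` — the descriptors
- `src/cdftfold/tica.py` — folding coordinate, kinetic maps, sampling
- `src/cdftfold/folding.py` — Δη, change-point classifier, summaries
- `src/cdftfold/synthetic.py` — generators for every input class
- `docs/methods.md` — models, conventions, parameter defaults,
  limitations
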