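# Methods

This note documents the models implemented in `cdftfold`, the
conventions and defaults chosen where the underlying theory leaves them
open, what the synthetic generators do and do not emulate, and the known
limitations.

## Electronic-structure model

All descriptors are computed from a single-determinant, closed-shell
molecular-orbital picture: MO energies, integer occupations, an AO × MO
coefficient matrix, an AO→atom map, and optionally the AO overlap
matrix.  Open-shell systems are rejected at load time rather than
mis-handled.  The canonical internal energy unit is eV (MOPAC-aux files
are native eV; Molden energies are converted at 1 hartree =
27.211386 eV).  One fixed unit matters because the energy-weighted
Fukui exponent is dimensionful (below).

The occupied/virtual boundary is an occupation threshold of 0.5
electrons — robust for the integer occupations in scope, and tolerant
of the fractional-occupation test constructions.  HOMO is the
highest-energy MO above the threshold, LUMO the lowest at or below it.

## Population analysis and condensation

Per-atom electron populations use Mulliken analysis:
ρ_A = Σ_{μ∈A} (P·S)_{μμ} with P = C·diag(occ)·Cᵀ.  When the source
provides no overlap (NDDO semiempirical outputs follow the
zero-differential-overlap convention) the diagonal form
ρ_A = Σ_{μ∈A} P_{μμ} is used; a Löwdin variant (S^½·P·S^½) is
available.  Orbital densities |ψ_i|² are condensed by the same scheme
and normalized to sum 1.  Residue condensation is a plain sum over
member atoms, so every conservation identity transfers from atoms to
residues exactly.

## Global descriptors

From the frontier energies: IP = −E_HOMO, EA = −E_LUMO,
μ = (E_HOMO+E_LUMO)/2, η = E_LUMO − E_HOMO (full gap, not half),
S = 1/η, ω = μ²S/2, nMax = −μ/η.  nMax uses the standard
maximal-electron-acceptance expression of the electrophilicity
framework, which is the only dimensionally consistent reading; it is
exposed as a named field so a different convention can be substituted
downstream.  A non-positive gap is an error, not a NaN.

## Fukui functions

- Frozen-orbital (FOA): f⁻ = condensed HOMO density, f⁺ = condensed
  LUMO density.
- Finite-difference: f⁻ = ρ_N − ρ_{N−1}, f⁺ = ρ_{N+1} − ρ_N, given
  three population fields over the same atoms.
- Energy-weighted (EW): occupied MOs within a window of the HOMO
  (virtuals within the window of the LUMO) contribute their condensed
  densities with weight exp(−|E_i − E_ref|), the energy difference in
  **eV**, and the sum is renormalized to 1.  Defaults: window = 1.0 eV.
  The window captures near-degenerate frontier manifolds — the reason
  the EW form exists for biopolymers — without flooding the sum with
  deep orbitals; at window = 0 the non-degenerate case reduces exactly
  to FOA, and a g-fold degenerate HOMO splits 1/g per localized site.
  Renormalization keeps ∫f dr = 1, so local softness sums to S and the
  Fukui-weighted hardness sums to η.

Composites: f⁰ = (f⁻+f⁺)/2 (sums to 1), f± = f⁺−f⁻ (sums to 0).
Local softness s_A = S·f_A; the f⁻/f⁺/f⁰ variants correspond to the
electrophilic/nucleophilic/radical attack-susceptibility measures
(EAS/NAS/RAS).

## Local hardness

Four condensed working definitions:

1. **TFD** (default for trajectory analysis):
   η_A = (1/2N)·Σ_{B≠A} ρ_B/r_AB.  Point-charge condensation of the
   Thomas–Fermi–Dirac electron–electron potential.
2. **Fukui potential**: η_A = Σ_{B≠A} f_B/r_AB (f⁻ by default; f⁺ and
   f⁰ variants accepted).
3. **LCP**: η_A = (ρ_HOMO,A − ρ_A/N)·μ/(2N) + (ρ_A/N)·η.  The first
   term telescopes to zero over atoms (Σρ_HOMO,A = 1, Σρ_A = N), so
   Ση_A = η exactly — the integration constraint this definition is
   designed around.  The printed forms of this expression in the
   literature are typographically ambiguous; the implementation is
   isolated in one function so the interpretation can be revised
   without touching callers.
4. **Fukui-weighted**: η_A = IP·f⁻_A − EA·f⁺_A, which sums to
   IP − EA = η for normalized inputs.

Conventions for 1–2: interatomic distances in bohr, outputs in atomic
units; the self term (B = A) is excluded because the point-charge 1/r
kernel diverges at zero distance (an on-site radius alternative could
replace the exclusion; the downstream analysis z-normalizes, so only
relative per-residue values matter).  Centers closer than 0.1 bohr are
rejected.  Neither the TFD form nor the Fukui potential integrates to
the global hardness — that is a property of the definitions, not an
implementation defect.

## Structural metrics

- **RMSD-Cα**: Kabsch superposition (centering, SVD of the
  cross-covariance, determinant-corrected rotation), over Cα atoms.
- **RMSF**: frames are superposed onto their Cα mean structure with one
  superpose/re-mean pass (iterating to convergence is available via
  `iterate=True`); RMSF(j) is the RMS displacement of Cα(j) about its
  mean.  The single-pass reference is a stated convention, not an
  inference.
- **Q, fraction of native contacts**: native contacts are residue pairs
  with sequence separation ≥ 3 whose minimum heavy-atom distance in the
  native structure is < 4.5 Å; a contact survives in a frame if that
  minimum distance stays < 1.2× its native value.  Hydrogens are
  excluded because H placement differs systematically between
  force-field and quantum-chemical structures; waters/ions are flagged
  at parse time and excluded from contacts.  All three constants are
  keyword arguments.

PDB parsing keeps the first alternate location, appends insertion codes
to the residue key, and infers elements from the element column with an
atom-name fallback — deterministic behaviour on real-world PDB
dialects.

## tICA folding coordinate

Backbone φ/ψ angles are embedded as (sin θ, cos θ) pairs, removing the
±180° discontinuity.  The estimator is symmetrized:
C(0) = (X₀ᵀX₀ + X_τᵀX_τ)/2(T−τ) and
C(τ) = (X₀ᵀX_τ + X_τᵀX₀)/2(T−τ), which guarantees a real generalized
spectrum with |λ| ≤ 1 (Cauchy–Schwarz), a bound the tests assert.
C(0) gets a default diagonal regularization of 1e−8·trace(C(0))/k so
duplicated or constant dihedral columns do not make the problem
singular.  Lag 0 is rejected (the problem degenerates to PCA).
Projections are eigenvalue-scaled by default ("kinetic map"), so
Euclidean distances approximate kinetic distances; raw projections are
a flag away.

Free-energy surfaces are −ln(count/max count) over a 2-D histogram of
(tIC1, tIC2); empty bins are masked, not infinite.  Sampling n frames
along tIC1 uses n equal-width bins, nearest-to-center within each
non-empty bin, and nearest-neighbour backfill for empty bins — an
explicit, reproducible rule with ordered, duplicate-free output.

## Δη and the fluctuation-stabilization classifier

The trajectory matrix (frames × residues, one descriptor) is referenced
to the frame of minimum RMSD-Cα: Δη_j^i = η_j^i − η_j^r.  Positive
cells mean harder than the folded reference.  The per-frame instability
score is the mean over residues of |Δη| (a rolling-SD score is
available); a single change point minimizes the pooled within-segment
sum of squares with both segments ≥ `min_segment` (default 5) frames.
One change point, not several, because the analysis partitions a
trajectory into exactly two regimes; the lower-mean segment is labeled
native-like regardless of trajectory direction, so folding-ordered and
unfolding-ordered trajectories are handled symmetrically.  A score
series whose two segments have equal means within tolerance yields a
`no_evidence` flag rather than a spurious boundary.

Matrix normalization for display/summary is global (subtract the grand
mean, divide by the max absolute deviation, landing in [−1, 1]) rather
than per-residue, so the ordering of residues by descriptor magnitude
is preserved across the matrix; per-residue scaling would erase exactly
the residue-type contrasts the profile summaries report.

Residue groups for the group/region summaries: (1) nonpolar aliphatic
ALA GLY ILE LEU MET PRO VAL, (2) aromatic PHE TRP TYR, (3) uncharged
polar ASN GLN SER THR, (4) positively charged ARG HIS LYS, (5)
negatively charged ASP GLU.  CYS is deliberately unassigned (its
thiol/disulfide chemistry fits none of the five classes cleanly) and is
reported only in the per-type profiles.

## Synthetic generators

- **Random electronic structures**: random orthogonal coefficient
  matrices (QR of seeded Gaussians); with a random symmetric
  positive-definite overlap the coefficients are back-transformed so
  CᵀSC = I.  Occupied energies are drawn in [−20, −5] eV with the HOMO
  pinned at −5 eV and a configurable HOMO–LUMO gap (default 4 eV,
  a mid-sized molecular gap).  Degenerate-HOMO variants localize the
  frontier pair on chosen atoms for exact EW-splitting tests.
- **Tight-binding chains**: E_k = α + 2β·cos(kπ/(n+1)),
  C_jk ∝ sin(jkπ/(n+1)), built from the closed form so they are
  analytic oracles rather than numerical fixtures.
- **Folding trajectories**: residue j's descriptor at frame i is
  baseline_j + N(0, σ²) with σ = σ_pre before the planted change point
  and σ_post after (defaults 1.0 and 0.1, a 10× stabilization, at 100
  frames × 20 residues with the change point at frame 60); baselines
  are N(10, 2²).  Gaussian noise is the minimal model carrying an
  amplitude parameter — the emulated phenomenon is the amplitude drop,
  not any particular noise distribution.  Cα geometry interpolates an
  extended chain into a compact helix-like spiral with the folding
  parameter advancing across the change point and reaching the compact
  reference exactly at the last frame, so the RMSD series used by Δη is
  computed by the package's own Kabsch RMSD, not assumed.
- **Two-state Markov series**: hidden ±1 chain with flip probability p
  (lag-τ autocorrelation (1−2p)^τ analytically), emitted into
  state-scaled feature means plus N(0, 0.1²) noise.

What the generators do **not** emulate: real force-field sampling,
solvation, realistic electronic structure of polypeptides, correlated
(non-white) descriptor noise, or gradual (non-step) stabilization.
Passing tests therefore demonstrate correctness of the estimators and
descriptor algebra under the stated statistical model, not that real
folding trajectories exhibit a sharp change point.

## Problem sizes and numerics

The test and acceptance runs use 1000 random systems of 4–6 atoms × 2
AOs for the conservation suite, 100 random 4–9 atom geometries for the
pairwise-potential oracles, 20000-frame series for tICA, and 50 seeds
of 100 × 20 trajectories for change-point recovery — sizes at which
every check is exact or tightly bounded while the whole suite runs in
seconds.  Tolerances: conservation identities to 1e−8 (they hold to
machine precision in practice), analytic oracles to 1e−10…1e−12,
stochastic estimates (tICA top eigenvalue, recovery rate) at the bounds
their sampling noise supports (±0.03 at n = 20000; ≥90% of 50 seeds).

## Known limitations

- Mulliken condensation is basis-set sensitive; Hirshfeld/Bader
  partitions are out of scope.
- The EW window (1.0 eV) and exponent unit (eV) are package
  conventions; other tools may weight differently, changing absolute
  (not usually relative) per-residue values.
- The condensed 1/r potentials treat atoms as point charges; on-site
  contributions are excluded rather than modelled.
- The change-point classifier assumes exactly one fluctuation regime
  change; multi-basin trajectories with several metastable segments
  need multi-change-point segmentation, which is deliberately not
  implemented.
- No DSSP, no trajectory formats (DCD/XTC), no implicit-solvent
  corrections; single-point outputs are upstream inputs, never run by
  this package.
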