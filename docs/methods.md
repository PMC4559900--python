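# Methods

## Inference: mean-field direct coupling analysis

The family alignment is modeled by a global Potts distribution over the 21
states (20 amino acids in alphabetical one-letter order, gap = state 0);
columns are indexed 0-based throughout.  The steps are the standard
mean-field ones:

- **Reweighting.** Sequence `s` receives weight `1/|{t : id(s,t) ≥ θ}|`
  with identity counted over all columns, gaps included, self included;
  `Meff = Σ w_s`.  Default θ = 0.8.  θ is a similarity threshold (a
  fraction, not a distance); setting θ = 1 keeps only exact duplicates
  clustered.
- **Frequencies.** `f_i(a) = (λ/q + Σ_s w_s δ) / (λ + Meff)` and the pair
  analog with `λ/q²`; the diagonal convention is
  `f_ii(a,b) = δ_ab f_i(a)`.  Default λ = `Meff`, the conventional
  mean-field pseudocount; λ > 0 guarantees an invertible correlation
  matrix.
- **Inversion and gauge.** The connected-correlation matrix is restricted
  to the first `q − 1` states of every column (the last alphabet state is
  the gauge state whose couplings are zeroed) and inverted once;
  `e_ij(a,b) = −(C⁻¹)` off-diagonal blocks.  Direct information is
  insensitive to the gauge because the two-site model re-imposes the
  empirical marginals.
- **Direct information.** The auxiliary fields of the two-site model are
  found by fixed-point (Sinkhorn-type) iteration, tolerance 1e−6 on the
  marginal mismatch, at most 500 iterations, damping 0.5 once the error
  increases.  The fixed point converges only linearly, and for sparse
  high-q statistics the rate can approach 1; in that case a quasi-Newton
  root find on the log-fields (scipy `hybr`) finishes from the warm start.
  Non-convergence of both routes is an error carrying the iteration
  diagnostics.  DI values below 1e−12 are clamped to exactly zero so that
  exact ties remain exact; ties are broken lexicographically by `(i, j)`.
- **Ranking.** All pairs with `j − i ≥ min_separation` (default 2).  The
  default deliberately keeps near-diagonal pairs: in homodimers genuine
  interface couplings can lie close to the diagonal, and the monomeric
  contact filter — not a sequence-separation heuristic — is the intended
  suppressor of intra-chain pairs.

## Filtering dimerization couplings

Order: surface-accessibility filter → top-N truncation → monomeric-contact
removal.  The order matters and is regression-tested.

- The SASA filter keeps a pair if `max(relSASA_i, relSASA_j) ≥ 0.5`
  (boundary included).  Relative SASA is Shrake–Rupley (probe 1.4 Å, 960
  Fibonacci points per atom by default) normalized by per-residue-type
  maxima (Tien et al. 2013); residues with unknown type or incomplete atom
  sets fall back to their isolated-atom area, which makes the same code
  path meaningful for synthetic dummy-sphere structures.  SASA is computed
  on a single monomer chain, not the dimer.
- `n_top` defaults to 100, matched to real protein families (it yields
  30–75 surviving couplings there; the pipeline warns outside [10, 150]).
  For the 30-bead toy fixture with its 8-coupling interface the tests use
  `n_top = 10` — with only 8 true couplings a top-100 truncation admits
  dozens of noise pairs that outnumber the signal.
- Monomeric removal is exact membership in the monomer Cα map at 8 Å
  (strict `<` at the cutoff).  An optional dilation δ removes pairs with
  monomer distance `< 8 + δ` for users who prefer a looser exclusion zone;
  default δ = 0.
- Survivors are symmetrized: each `(i, j)` yields restraints `(i_A, j_B)`
  and `(j_A, i_B)`, reflecting the two-fold symmetry of homodimeric
  interfaces.  Self-pairs `(i, i)` are structurally excluded — a coupling
  of a column with itself is undetectable by coevolutionary inference.
  Every input pair receives one provenance record naming the single filter
  that removed it, or `kept`.

## The structure-based model

Cα beads, reduced units: ε = 1 energy unit, bead mass 1, time unit τ,
k_B = 1.

| term | form | default |
|---|---|---|
| bond | ½ k_b (r − r⁰)² | k_b = 200 ε/Å² |
| angle | ½ k_a (θ − θ⁰)² | k_a = 40 ε/rad² |
| dihedral | k_d [(1−cos Δφ) + ½(1−cos 3Δφ)] | k_d = 100 × 1 ε |
| native / restraint contact | ε(σ/r)¹² − A ε e^{−(r−r⁰)²/2w²} | σ = 4 Å |
| other pairs | ε(σ/r)¹² | — |

Equilibrium values come from the native monomer geometry.  The ×100
dihedral stiffening keeps monomers near-rigid while they translate and
reorient; the absolute bonded constants are conventional Cα-model
magnitudes (the ratio is what matters).  Intra-chain native contacts
(monomer map at 8 Å, `|i − j| ≥ 4`) get narrow wells, A = 1, w = 0.5 Å, at
native distances.  Excluded volume uses one uniform bead diameter; bonded
and contact pairs are excluded from the generic repulsion list.

### Annealing schedule

Seven stages; the restraint wells' `(r^N, A, w)` are reloaded between
stages:

    r^N (Å): 50  38  28  20  14  10   8
    w   (Å): 10   8   6   5   4   3   1.5
    A      :  1   1   1   1   2   3   4

The endpoints (50 Å → 8 Å) anchor the plan; intermediate distances
interpolate them roughly geometrically with each gap within ~1.7 w of the
next stage's well so the chains are always inside the capture range.
Widths shrink as orientational search gives way to interface locking, and
the amplitude ramps only over the last three stages to stabilize the final
complex.  `w` is interpreted as the Gaussian standard deviation (a wider
well — larger w — admits more conformations at a given energy).  All seven
triples are config-overridable, so an exact externally specified plan can
be reproduced verbatim.

## Dynamics and convergence

BAOAB Langevin integration, one force evaluation per step; at γ = 0 the
scheme reduces to velocity Verlet (used for energy-conservation checks;
measured secular drift at dt = 0.0005 τ over 1e5 steps is ~6e−5 ε).
Defaults: dt = 0.005 τ, γ = 0.1 τ⁻¹, T = 0.3 ε, stage budget 1e5 steps,
recording stride 50.

- The stability margin at dt = 0.005 is set by the bond frequency
  ω = √(2k_b) = 20 τ⁻¹, giving ω·dt = 0.1.
- Friction is deliberately light.  The chain centroids move at terminal
  speed ~F/(γ N m); at γ = 1 τ⁻¹ two 30-bead chains cannot traverse the
  50 Å separation within any reasonable stage budget, while γ = 0.1
  crosses it in ~2×10⁴ steps and still dissipates the capture transients.
- T = 0.3 ε is well below the model's folding temperature; at T = 0.5 the
  capture collisions transiently deformed toy monomers to ~2.2 Å internal
  RMSD, against the intent that monomer conformations stay essentially
  fixed (with T = 0.3 the worst excursion is ~1.9 Å and the docking
  accuracy improves).

**Per-stage convergence.**  The monitored series is the RMSD to the native
complex in validation mode and the total restraint energy in blind
prediction (where no reference exists).  A stage stops when, over a
window of 50 recorded frames, both the standard deviation and the
split-half drift of the series fall below 2% of the running mean — the
drift test matters because a slowly approaching pair of chains produces a
low-variance but trending series.  The test is armed only once the mean
restraint distance is inside `r^N + 2w`; on the flat tail of the Gaussian
the series is stationary while the chains are still far apart, and
without the guard every stage "converges" immediately.  A stage that
exhausts its budget is flagged and the protocol continues — the stage
count is fixed by design.  Stage transitions reuse velocities (no
re-thermalization); this keeps the annealing smooth and is trivially
toggled by re-drawing `state.v`.

One practical note: the stage-end restraint energy is *not* monotone over
the four equal-amplitude stages — each stage stops at a depth that depends
on how far into its (progressively narrower) well the chains settled.
What the protocol does guarantee, and what the tests assert, is strict
deepening over the amplitude ramp and a global minimum at stage 7.

## Evaluation

- Superposition is least-squares (Kabsch via SVD) with the proper-rotation
  correction; rotationally degenerate (collinear) point sets are rejected.
- Dimer RMSD is computed for both chain assignments of the homodimer and
  the minimum is returned; chain labels carry no information for identical
  chains.
- Interfacial RMSD: interface residues are native residues with any
  cross-chain Cα within 10 Å (CAPRI-style); the superposition is computed
  on the interface residues only, chain-swap minimized.  The definition is
  a package choice — no standard fixes it uniquely — and the cutoff is
  configurable; absolute iRMSD values depend on it.
- "Best" frame = minimum whole-complex RMSD over the trajectory
  (validation mode only).  Contact recovery is the fraction of native
  inter-chain 8 Å contacts reproduced within 8 Å in the best frame.

## Synthetic data: what it does and does not emulate

The Potts sampler (vectorized multi-chain Gibbs sweeps; burn-in 300
sweeps, thinning 5, seeded) emulates equilibrium family statistics with
planted couplings `J_ij(a,b) = 2 δ_ab`.  It does **not** emulate phylogeny
(sequences are exchangeable, so reweighting is nearly inert at θ = 0.8),
alignment errors, gap patterns of real families, or fields/composition
bias.  The toy dimer is two identical idealized helices (rise 1.5 Å,
radius 2.3 Å, 100° twist) related by a proper two-fold rotation, packed by
a separation scan until the requested number of distinct interface pairs
appears at 8 Å; beads carry dummy spheres sized so that a fully exposed
bead has relative SASA 1.  Passing the end-to-end test therefore shows
that the inference–filter–dock–score chain is internally correct and that
the annealing protocol reliably reassembles a complex whose interface
couplings are recoverable; it does not show that real Pfam-scale families
with phylogenetic structure, or proteins with flexible interfaces, reach
the same accuracy.

Problem sizes used by the test suite and the acceptance script — chosen as
the smallest that leave comfortable statistical margins: alignments of
M = 2000–3000 sequences at L = 30, q = 8 for recovery studies (recovery is
10/10 planted pairs at these sizes); exact-oracle DI checks at q = 2,
L = 3; docking studies on 2 × 30 beads over 5 seeds.

## Mapping real data

Alignment columns are mapped to structure residues either by an external
two-column table (the recommended route: derive it from `hmmscan` output)
or by a global pairwise alignment (match +1, mismatch −1, gap −2) of the
alignment's column-consensus sequence against the structure sequence.
Coverage below 30% is treated as a wrong family/structure pairing and is
an error.  DI pairs touching unmapped columns are dropped and logged.

## Known limitations

- The mean-field approximation itself: couplings are a first-order
  inverse-covariance estimate; no pseudolikelihood or Boltzmann-machine
  refinement, and no average-product correction (DI ranking only).
- Monomers are treated as rigid except for harmonic flexibility; induced
  fit on binding is out of reach of the model.
- Couplings that are simultaneously monomeric and dimeric are removed by
  design; interfaces whose contacts are all of this kind would lose their
  restraints.
- The homodimer symmetrization presumes a two-fold-symmetric interface;
  asymmetric (domain-swapped) homodimers violate it.
- Blind-prediction convergence uses restraint energy, which cannot detect
  convergence to a wrong but restraint-satisfying pose; with few or noisy
  restraints, multiple poses can satisfy them.
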