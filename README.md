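# coevdock

Coevolution-driven docking of homodimeric protein complexes.

Residue pairs that are in contact across the interface of a homodimer
coevolve just like residue pairs that are in contact within a monomer, so
the inter-chain signal in a protein-family alignment is mixed in with the
much larger intra-chain signal — and, for a homodimer, both chains map to
the *same* alignment columns, so the two kinds of coupling cannot be told
apart from sequence alone.  `coevdock` implements the strategy of using the
known monomer structure as the separator: infer directly coupled residue
pairs from the family alignment, discard those explained by the monomer
(buried residues, intra-chain contacts), and drive a coarse-grained docking
simulation with the survivors as inter-chain restraints.

The pipeline, for users with a family alignment and a monomer/dimer
structure:

1. **mfDCA** — mean-field direct coupling analysis.  Sequences are
   reweighted at similarity threshold θ (default 0.8) to give an effective
   count `Meff`; single-site and pair frequencies `f_i(a)`, `f_ij(a,b)` are
   regularized with pseudocount mass λ (default `Meff`); couplings come
   from the mean-field inversion `e_ij(a,b) = −(C⁻¹)_{ij}(a,b)` of the
   connected-correlation matrix `C = f_ij − f_i f_j`; each pair is scored
   by its **direct information**

   `DI_ij = Σ_ab P_dir(a,b) ln [ P_dir(a,b) / (f_i(a) f_j(b)) ]`,

   where `P_dir ∝ exp(e_ij) h̃_i h̃_j` is the two-site model with the
   empirical marginals re-imposed.
2. **Filtering** — keep a pair only if at least one residue has relative
   solvent accessibility ≥ 50% (Shrake–Rupley SASA on the monomer); take
   the top 100 DI pairs; remove pairs that are contacts in the monomer's
   Cα map at 8 Å.  Survivors `(i, j)` are symmetrized into inter-chain
   restraints `(i_A, j_B)` and `(j_A, i_B)`.
3. **Docking** — a Cα structure-based model holds each monomer near its
   native geometry (bonds, angles, 100×-stiffened dihedrals, narrow
   Gaussian wells on native contacts); the restraints become Gaussian
   wells `V(r) = ε(σ/r)¹² − A ε exp(−(r−r^N)²/2w²)` whose equilibrium
   distance `r^N`, amplitude `A` and width `w` follow a seven-stage
   annealing schedule from `r^N = 50 Å` down to `8 Å`.  Starting from the
   two monomers separated by 50 Å and rotated 180°, BAOAB Langevin
   dynamics runs each stage until the monitored series stabilizes.
4. **Evaluation** — dimer RMSD (chain-swap minimized, as chain labels are
   arbitrary for identical chains), CAPRI-style interfacial RMSD over
   native-interface residues (10 Å cross-chain cutoff), best-frame
   selection and contact-map recovery reports.

A synthetic-data module generates the full study at desk scale: toy
homodimers (two identical helices related by a proper two-fold rotation,
with a controllable interface) and Potts-sampled alignments in which the
toy's interface pairs are planted as couplings — so the entire pipeline is
testable end to end against a known native complex, with no downloads.

## Worked example

```python
from coevdock.synth import build_toy_dimer, plant_interface_couplings, sample_potts
from coevdock.dca import run_dca
from coevdock.structure import build_initial_pose, contact_map, sasa
from coevdock.filtering import filter_pipeline
from coevdock.sbm import build_topology, default_schedule
from coevdock.simulate import run_annealing
from coevdock.evaluate import evaluate_trajectory

toy = build_toy_dimer(n=30, interface_size=8, seed=0)
model = plant_interface_couplings(toy, q=8)
msa = sample_potts(model, M=3000, seed=11)

ranking, freq, coupling = run_dca(msa)
mono = toy.monomer("A")
restraints = filter_pipeline(ranking, sasa(mono), contact_map(mono, 8.0),
                             sasa_threshold=0.0, n_top=10)

topology = build_topology(mono, toy.native.select_chains(["B"]), restraints)
pose = build_initial_pose(toy.native, separation=50.0, seed=100)
traj = run_annealing(pose, topology, default_schedule(), seed=0,
                     mode="validate", native=toy.native)
report = evaluate_trajectory(traj, toy.native)
```

Output:

```
Meff = 3000
top-8 DI pairs recover 8/8 planted couplings
7 couplings survive filtering -> 14 inter-chain restraints
rmsd_best = 0.60 A at frame 4313
irmsd_best = 0.62 A
final-stage mean RMSD = 1.07 A
```

All eight planted interface couplings rank at the top of the DI list; one
of them, lying inside the monomer's own contact map, is (by design)
removed by the monomeric filter; the remaining seven, symmetrized into 14
restraints, pull the randomized, 50 Å-separated monomers back to within
0.6 Å of the native complex.  The `n_top=10` truncation here is scaled to
the toy's 8-coupling interface; for real protein families the default is
the conventional top 100.

The same pipeline is scriptable from the shell:

```
coevdock synth --n 30 --interface-size 8 --out fixture/
coevdock run --alignment fixture/alignment.fasta --structure fixture/native_dimer.pdb \
             --mode validate --out run/
```

`run/` then contains the DI table, restraint list with per-pair filter
provenance, the serialized topology, the annealing trajectory with
per-frame energies, the evaluation report and a manifest from which the
run can be reproduced exactly.

## Scope

The package operates on user-supplied alignments and structures; it does
not download Pfam families or PDB entries, re-implement profile-HMM
scanning (feed `hmmscan`-derived column↔residue tables via
`--mapping-table`), model missing loops, or handle heterodimer /
multi-domain interface inference.
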