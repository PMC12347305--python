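# torsionfold

Fragment-assembly tertiary-structure prediction for peptides, refined by a
hybrid global optimizer: simulated annealing on a golden-section cooling
schedule whose trial moves come from a jumping-spider population search.
It is aimed at people studying torsion-space conformational optimization of
short peptides (roughly 9–50 residues) who want a small, fully inspectable,
seeded-and-reproducible pipeline rather than a production folding server.

## The method

A peptide conformation is the torsion vector
S = [φ₁, ψ₁, χ₁, ω₁, …, φₙ, ψₙ, χₙ, ωₙ] (degrees); covalent bond lengths
and angles are rigid. The objective is an ECEPP-style in-vacuo potential

E = Σ_{j>i} (A_ij/r_ij¹² − B_ij/r_ij⁶) + 332 Σ_{j>i} q_i q_j/(ε r_ij)
  + Σ_{hb} (C_ij/r_ij¹² − D_ij/r_ij¹⁰) + Σ_n U_n (1 ± cos k_n φ_n)

with r_ij in Å and energies in kcal/mol. Prediction runs in three stages:

1. **Fragment prediction.** The target sequence is cut into consecutive,
   non-overlapping six-residue windows (a 32-mer gives five windows and a
   2-residue remainder). A predictor maps each window to its 18 backbone
   torsions (6 φ, 6 ψ, 6 ω). Two backends: a small 1-D convolutional
   network (four conv layers of kernel 4, ReLU, dropout 0.1, max-pool 2,
   dense 128 and 256, 18 outputs; Adam on MSE, batch 8, 80/20 split)
   trained on a fragment library, and a deterministic nearest-sequence
   lookup for fully reproducible runs without training. A seeded synthetic
   library generator (helix/strand/loop classes around their canonical
   Ramachandran basins) makes the whole pipeline testable offline.
2. **Assembly.** Window predictions are concatenated into a preliminary
   torsion model; remainder residues and all side-chain χ angles are drawn
   uniformly at random for the refinement stage to fix.
3. **Refinement.** Annealing over temperature sections whose boundaries
   shrink by Φ = 0.618 per section while the cooling factor α steps
   0.75 → 0.95, so cold sections search longest. Each Metropolis step asks
   a short spider-population search (persecution, projectile jump,
   local/global search around the incumbent best, pheromone-based
   replacement of weak agents) for its candidate, then applies Boltzmann
   acceptance. A least-squares slope criterion on the trailing best-energy
   series stops the final section at stochastic equilibrium.

Predictions are scored against a reference with Kabsch-superposed Cα RMSD,
TM-score and GDT-TS.

## Worked example

Predict a toy 12-mer with the bundled synthetic library and the default
desk-scale configuration (two runs here; each run is an independent seeded
refinement):

```
$ torsionfold predict --fasta GAGAGAGAGAGA --runs 2 --seed 11 --out demo
sequence target (12 aa), 2 runs
  run 1: energy     100.42 ->      57.10 kcal/mol
  run 2: energy     101.87 ->      54.78 kcal/mol
best energy 54.78 kcal/mol; mean of best 2: 55.94 kcal/mol
outputs in demo/ (manifest.yaml, pred_run*.pdb)
```

The two energies per run are the assembled initial model and the refined
model; refinement never ends above its start. `manifest.yaml` records the
seeds, configuration and library fingerprint, and rerunning it reproduces
the PDB outputs byte for byte. Comparing the two runs' structures:

```
$ torsionfold score --pred demo/pred_run1.pdb --native demo/pred_run2.pdb
rmsd    tm_score        gdt_ts  n_residues      d0
0.8790  0.5050  0.8958  12      0.5000
```

i.e. the two independent refinements land < 1 Å apart, with ~90% of
residues within the GDT distance thresholds. Other subcommands:
`refine` (skip the fragment stages), `make-fragments` (write a synthetic
library), `train-predictor` (fit the convolutional backend).

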