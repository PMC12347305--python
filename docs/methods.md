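# Methods

This note documents the models, defaults and numerical choices behind
torsionfold, and what the bundled synthetic data can and cannot show.

## Conformational model

A peptide is represented purely in torsion space: per residue φ, ψ, the
rotatable side-chain angles χ₁..χ_c, and ω, flattened in that order. All
angles are degrees in [−180, 180); wrapping maps the boundary +180 to
−180. Covalent geometry is rigid: bond lengths (N–Cα 1.47 Å, Cα–C 1.53 Å,
C–N 1.32 Å, C=O 1.24 Å, N–H 1.00 Å) and bond angles come from the bundled
topology table, so Cartesian coordinates are a deterministic function of
(sequence, torsions). Atoms are placed by sequential
natural-extension-of-reference-frame construction in a fixed frame (first
N at the origin, first Cα on +x, with a virtual predecessor carbonyl
carbon defining φ₁). Backbone dihedrals measured from built coordinates
reproduce the inputs to ≤ 1e−6°; the last residue's ω is carried in the
vector for layout uniformity but moves no atom.

The residue topology is a deliberately simplified united-atom model:
backbone N, H, Cα, C, O plus a linear chain of united side-chain
pseudo-atoms, one more atom than the residue's rotatable-χ count so every
rotatable bond moves something. Methyl-bearing residues therefore carry a
terminal rotor (alanine has one χ), and ring side chains are approximated
by short linear chains. Proline keeps an amide H for topological
uniformity. This topology is illustrative, not a reproduction of any
published force-field geometry; both the topology and the energy tables
are pluggable text files.

## Energy

The objective is the ECEPP-form in-vacuo sum of 12-6, Coulomb
(constant 332 kcal·Å/(mol·e²), dielectric ε = 2.0), 12-10 hydrogen-bond
and torsion-barrier terms, a pure function of the torsion vector.
Decisions where the functional form alone does not fix behaviour:

* **Exclusions.** Pairs separated by one or two covalent bonds are
  excluded; 1-4 and beyond enter at full weight (the common rigid-geometry
  convention; configurable).
* **Hydrogen bonds.** For flagged donor-H/acceptor class pairs (amide H
  with carbonyl O in the bundled tables) the 12-10 term replaces the
  pair's 12-6 term. An additive mode that sums both unconditionally — the
  literal reading of the printed functional form — is available
  (`hbond_mode="additive"`).
* **Parameters.** The bundled table is reduced (six atom classes) with
  12-6 constants derived from per-class well depths/radii and a single
  H···O 12-10 well (r* ≈ 1.9 Å, depth ≈ 2 kcal/mol); torsion barriers use
  threefold backbone/χ terms and a twofold 20 kcal/mol ω term that keeps
  the peptide bond near planarity while leaving it free to rotate.
  Lookups are explicit: a missing pair or charge is a configuration
  error, never silently combined.
* Atom pairs closer than 1e−6 Å raise a numeric error naming both atoms.

## Fragment stages

Windows are non-overlapping and left-anchored; L mod 6 trailing residues
are the remainder (a 32-mer → five windows + 2). The predictor returns
exactly 18 backbone angles; χ angles are always randomized at assembly
since the 18 outputs cover only φ/ψ/ω.

The convolutional backend one-hot encodes the window (6×20, canonical
amino-acid order) and scales angle targets to [−1, 1] by /180. Layer
widths not fixed by the architecture description (four conv layers,
kernel 4, ReLU, dropout 0.1, pool 2, dense 128/256, 18 outputs) default
to 32 filters per conv layer. Training: Adam (lr 1e−3), MSE, batch 8,
80/20 split, 200 epochs by default (tests use a few epochs on small
libraries). The network is a compact numpy implementation with
finite-difference-verified gradients.

The synthetic library generator emulates only the *statistics* a fragment
library contributes: per-class torsion basins — helix (−57, −47), strand
(−139, 135), loops uniform over a permissive φ band — Gaussian angular
noise (default sd 5°), ω near 180°, and uniform random six-mer sequences.
It does **not** emulate sequence–structure correlation: which angles a
window receives is uncorrelated with its amino acids. Tests passing on
synthetic libraries therefore demonstrate the plumbing, calibration and
optimization behaviour of the pipeline, not predictive accuracy on real
proteins; for that a PDB-derived library must be supplied through the
fragment-library format. The default desk mix (124/100/36
alpha/beta/loop) keeps the class proportions of realistic fragment
collections at about 1/100 scale.

## Optimizer

* **Cooling.** Section boundaries are T₀·Φ^s with Φ = 0.618, at most five
  sections, α stepping 0.75 → 0.95 by 0.05 (an alternative convention
  starts at 0.70; both are supported, 0.75/five-sections is the default).
  Within a section T multiplies by α per cycle. The classical
  iteration-count formula n = −C/ln α with C = ln T_f − ln T₀ is negative
  as printed in some sources; it is implemented as
  ⌈ln(T_f/T₀)/ln α⌉ — the count of decrements taking T₀ to T_f.
* **Temperatures.** T₀ defaults to calibration: sample 100 random
  spider-strategy moves from the start and set T₀ = ⟨ΔE₊⟩/ln(1/0.9) for
  ~90% initial uphill acceptance; T_f = 1e−3·T₀.
* **Metropolis.** Length L_k is constant per cycle, default
  max(50, 2·dim); the desk pipeline overrides it to 6 for minutes-scale
  runs. ΔE ≤ 0 always accepts; uphill accepts with probability
  e^(−ΔE/T). An `as_printed` acceptance mode reproducing the inverted
  comparison (accept when e^(−ΔE/T) < u) exists for fidelity studies.
* **Stop criterion.** The trailing k_max = 5 per-cycle best energies are
  fit by least squares; the final section stops when |slope| < 1e−3
  (kcal/mol per cycle). The literal simplified slope formula found in
  some transcriptions drops the first point and yields 0.6 for a constant
  unit series; it is available as `slope_mode="as_printed"`, while the
  default is the corrected ordinary least-squares slope.
* **Spider search.** Each Metropolis candidate comes from a fresh
  population of 10 agents (the incumbent plus nine copies jittered by
  σ = 10°) run for 20 iterations. Per agent and iteration a fair coin
  picks attack vs search, a second coin the variant:
  persecution x ← ½(x_i − x_r) (r random ≠ i); projectile jump
  x ← x·tan α − x²·g/(2V₀²cos²α) with α = φπ/180, φ ~ U(0,1), V₀ = 100,
  g = 9.80665 (the printed numerals, units taken at face value);
  local x ← x_best + walk(½ − ε), walk ~ U(−2, 2), ε ~ N(0,1)
  (a U(0,1) reading of ε is configurable); global
  x ← x_best + (x_best − x_worst)λ, λ ~ Cauchy(0,1). All updates are
  element-wise with scalar draws per move, wrapped into bounds. Pheromone
  rates min-max-normalize fitness to [0,1] (all-equal populations rate 1,
  so nothing is replaced when there is no ranking information); agents at
  ≤ 0.3 are repositioned at x_best + ½(x_r1 − (−1)^σ x_r2). The
  best-ever agent is returned, so a candidate is never worse than the
  best of its own initial population.

## Metrics

RMSD uses the Kabsch least-squares proper rotation (via
scipy's rotation alignment); all-coincident point sets fall back to a
translation-only superposition with the identity rotation. TM-score uses
d0 = 1.24(L−15)^⅓ − 1.8 Å, floored at 0.5 Å where the formula is
non-positive (L ≤ 18), and both TM-score and GDT-TS (thresholds 1/2/4/8 Å,
normalized to [0,1]) are maximized over a reduced superposition pool:
global Kabsch plus sliding windows of length L, L/2 and L/4, each
iteratively refined on residues currently within d0. This is a standard
reduced search; it can only underestimate the exhaustive optimum.
Metrics are computed on index-matched Cα atoms; no alignment is done.

## Problem sizes and reproducibility

Desk defaults are chosen for minutes-scale single-CPU runs: a ~12-residue
target, three independent seeded runs by default (the report averages the
best five when five or more exist), Metropolis length 6 in the pipeline
configuration, and the full 10×20 spider search per step. The quadratic
recovery experiment follows a 30-seed protocol (a scaled-down analogue of
common 30-run benchmarking practice) on a separable 5-variable quadratic
with bounds [−180, 180). Every random draw flows from one master seed via
seed sequences, so manifests reproduce runs bit for bit.

## Limitations

In-vacuo energies ignore solvent; the reduced parameter set is
illustrative, not a validated force field; the united-atom topology
distorts branched and ring side chains; the synthetic fragment library
carries no sequence signal; and the TM-score/GDT-TS search pool is an
approximation to the exhaustive reference procedures. The package's
claims are correspondingly about algorithmic behaviour (calibration,
contracts, convergence on known optima, reproducibility), not about
accuracy against experimental structures.
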