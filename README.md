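# copolyscan

Enumeration-selection design of lattice copolymers: exhaustively score every
candidate sequence of an amphiphilic chain by Monte Carlo sampling in fixed
mean fields, then rank them by a design criterion — mean membrane
translocation time, or localization inside a core-shell micelle.  The same
machinery anneals reversible degrees of freedom (hydrogen-bond placement
along a chain, branch-point topology) against concentration gradients.

The package is aimed at polymer physicists and soft-matter modellers who
want a transparent, reproducible inverse-design baseline: instead of a
heuristic search, solve the *direct* problem (one cheap single-chain
simulation) for every point of the design space and sort.

## Model

Chains are self-avoiding walks on a cubic lattice with a 26-vector bond set
(all nonzero vectors with components in {−1, 0, +1}).  The box is periodic
in x, y and bounded in z.  Monomers are hydrophobic (T) or hydrophilic (H)
and interact only with three frozen volume-fraction fields — lipid tails
Φ_T, head groups Φ_H, solvent Φ_S (Φ_T + Φ_H + Φ_S = 1 per site) — via a
contact Hamiltonian in units of k_BT:

    H(Γ) = Σ_monomers Σ_fields ε[type, field] · U[type, field](Γ)

with defaults ε_{T−H} = ε_{H−T} = ε_{T−S} = 0.1 k_BT and all other contacts
athermal.  Conformations Γ are generated by Rosenbluth growth and carry the
weight w_Γ = Π_k n_free(k)/26, so ensemble averages are Boltzmann sums
Σ_Γ w_Γ e^{−H(Γ)}.  Because the fields are frozen, every conformation is
independent: sequences can be scored in any order or in parallel with
bitwise-identical results (counter-based per-sequence RNG substreams).

Design observables:

* **F(z)** — layer free energy, −ln Σ w_Γ e^{−H} over chains whose center
  of mass lies in layer z (relative to the membrane mid-plane);
* **τ** — mean first escape time across F(z), the discrete Kramers double
  sum τ = Σ_z e^{F(z)} Σ_{z′≤z} e^{−F(z′)} (units: lattice²/self-diffusion
  constant), used to rank translocating sequences;
* **θ_MD** — localization score, the summed mean concentrations of chosen
  monomers inside a chosen radial shell of a spherical core-shell field;
* two-state H-bond annealing (exact enumeration of all bond placements at
  fixed composition, Boltzmann-weighted in a radial density field) and
  radial branch-point profiles of branched Rosenbluth growth.

## Worked example

Rank all 70 balanced sequences of a length-8 chain by membrane escape time
(2·10⁵ conformations each, a few seconds):

```bash
cat > scan.cfg <<EOF
n = 8
n_tail = 4
samples = 200000
seed = 42
EOF
copolyscan translocate --config scan.cfg --out ranking.tsv
```

`ranking.tsv` (abridged):

```
rank  sequence  tau         stderr      n_samples
1     THTHTHTH  610.088882  3.42240629  200000
2     HTTHTHTH  610.564634  3.72007013  200000
...
69    TTTTHHHH  4576.11362  100.29845   200000
70    HHHHTTTT  4704.12489  82.953986   200000
```

Strictly alternating patterns translocate fastest (τ ≈ 610, barely above
the free-diffusion value 528 for a flat 32-layer profile), because short
blocks localize only weakly at the bilayer–solvent interfaces; diblocks are
~8× slower already at N = 8, and the gap grows exponentially with chain
length.  The same library calls are available in Python:

```python
import copolyscan as cps
prof = cps.sample_free_energy_profile(
    cps.Sequence.from_string("T"*12 + "H"*12), samples=1_000_000, seed=1)
print(cps.barrier_height(prof).barrier)   # ~18.9 kBT desorption barrier
print(cps.mean_escape_time(prof).tau)
```

Other subcommands: `copolyscan localize` (micelle θ_MD ranking),
`copolyscan hbond` (two-state annealing profiles), `copolyscan branch`
(branch-point distributions), `copolyscan fixtures` (deterministic tiny
oracle scenarios).  All outputs are TSV with metadata headers plus a
provenance sidecar (seed, config hash, dead-end fraction); conformations
dump as standard XYZ.

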