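# Methods

## Model

A polymer is a chain of unit-cube monomers on a simple cubic lattice.
Bonded monomers differ by one of the 26 vectors obtained from (1,0,0),
(1,1,0), (1,1,1) by permutations and sign changes, so a site interacts with
at most z = 26 nearest neighbors.  Excluded volume is hard: one monomer per
site, and a site holds either a monomer or field/solvent
(incompressibility).  There is no intra-chain energy beyond excluded
volume, no electrostatics, and no monomer–monomer pair potential: all
energetics are monomer–field contacts,

    H(Γ) = Σ_i Σ_f ε[type(i), f] · U_f(i, Γ)        [k_BT, β = 1]

where U_f(i, Γ) is the (possibly fractional) number of field-f contacts
over the unoccupied sites of monomer i's 26-neighborhood.  Neighbor sites
occupied by the same chain contribute nothing; neighbor sites outside the
z-range contribute nothing (consistent with blocked-site growth below).
The default interaction map is ε_{T−H} = ε_{H−T} = ε_{T−S} = 0.1 k_BT with
every other pair athermal, which makes an all-T chain fully hydrophobic and
an all-H chain fully hydrophilic.

Fields are *frozen* (quasi-instantaneous mean-field approximation).  No
self-consistent update is performed; conformations are therefore
statistically independent, which is what makes exhaustive sequence scans
embarrassingly parallel.  The price is the usual mean-field neglect of
inter-chain correlations.

### Geometries

* **Planar membrane** (default box 32×32×32, z ∈ [−16, 15], periodic in
  x, y): a 6-layer hydrophobic tail slab centered in the box, flanked by
  2 head-group layers per side, solvent elsewhere.  With an even slab the
  mid-plane falls between two lattice layers (z = −0.5 in absolute
  coordinates); all reported z are relative to it.  The 32-layer height
  matches the free-diffusion escape time τ ~ |2z|² ~ 10³.
* **Spherical micelle**: hydrophobic core of radius 13 lattice units from
  the box center, hydrophilic shell of thickness 3, solvent beyond.  A site
  belongs to radial shell ⌊r⌋ for profile reporting (matching the integer
  shell bounds of the localization criteria, e.g. 0 < r < 2 → shells
  {0, 1}).
* **Sigmoid globule**: radial polymer density φ_p(r) = A − A/(1 + e^{−r+r₀})
  with r₀ = 9; A = 1 (dense) or 0.5 (sparse).  Used by the H-bond and
  branching analyses, with solvent fraction 1 − φ_p.

## Sampling

Conformations are generated by classic Rosenbluth growth: the first monomer
uniform over the box, each next monomer uniform over the unoccupied
26-neighbor sites of its parent, weight w = Π_k n_free(k)/26 ∈ [0, 1]
(normalized-atmosphere convention, so an unobstructed dimer has w = 1; any
fixed rescaling cancels in all Boltzmann ratios).  Growth attempts outside
the z-bounds count as blocked sites.  Dead ends keep w = 0, stay in the
sample count (unbiased estimator) and are never regrown.  No pruning or
enrichment (PERM) is used: at these chain lengths (N ≤ 24) dead ends are
rare and plain Rosenbluth sampling is adequate.

Under this scheme every self-avoiding walk is generated with probability
(1/V)·Π 1/n_free and w·P(Γ) is constant, so Σ w e^{−H} estimates the plain
enumeration sum Σ_Γ e^{−H} up to a known constant.  The test suite exploits
this: for N ≤ 3 in a 5³ box all walks are enumerated outright and the
sampled F(z), concentrations and escape time must agree within 3 standard
errors, including the analytically known normalization offset.

**Randomness.**  One master seed spawns counter-based splitmix64 substreams
per (sequence, sample index).  Per-sequence work is order-insensitive and
side-effect free, so removing sequences from a scan or reordering it never
changes the remaining scores, and the same seed reproduces results bitwise.
The identical integer recurrence is implemented in the numba kernels and in
the pure-Python growers; a test pins both to the same stream.

## Observables and conventions

* **F(z)**: conformations are binned by center of mass z̄ into the unique
  integer layer with |z̄ − z| < ½; ties at exactly ½ go to the lower bin.
  F = −ln Σ_bin w e^{−H}.  An empty bin raises by default (it can be set to
  report +∞).  All exponential sums are computed relative to the profile
  midrange (log-sum-exp discipline).
* **Escape time**: τ = Σ_z e^{F(z)} Σ_{z′≤z} e^{−F(z′)} with dz = 1 and the
  inner sum inclusive; exactly M(M+1)/2 on a flat M-bin profile and
  invariant under F → F + const to machine precision.  The
  length-dependence of the diffusion constant is *not* modelled; τ is in
  units of the monomer self-diffusion time.
* **Desorption barrier**: solvent-plateau F minus global minimum.  The
  plateau is averaged over bins with 8.5 ≤ |z| ≤ 12.5 — beyond the head
  groups (|z| > 5) by roughly one chain radius, and clear of the last ~3
  layers near the hard z-walls where the center-of-mass binning depletes
  and distorts F.  The effective coordination number follows as
  z_eff = F_barrier/(ε_{T−S}·N_T).
* **θ_MD**: Σ_{i∈M} Σ_{s∈D} C̄_i(s) over an arbitrary monomer index set M
  (1-based) and shell set D (shells overlapping the open interval
  (r_lo, r_hi)); C̄_i is the Boltzmann-averaged indicator concentration,
  normalized so Σ_shells C̄_i = 1, hence θ_MD ≤ |M|.
* **Statistical errors** come from batch means over ≥ 20 batches
  everywhere (per-bin F errors by the delta method, τ errors on ln τ,
  per-batch θ for localization).

## Two-state hydrogen bonding

A chain of N = 16 monomers carries a fixed 50 % composition of H-bonded
(hydrophilic) vs free (hydrophobic) states whose *positions* anneal: all
C(16, 8) = 12870 assignments are enumerated exactly and weighted by
Σ_Γ w_Γ e^{−H} over a shared conformation sample in the radial density
field.  The state energies are not fixed by the reference ε table; this
package mirrors the membrane magnitudes: an H-bonded monomer pays
0.1 k_BT per contact with the polymer-density field, a free monomer
0.1 k_BT per solvent contact (configurable).  The annealed chain represents
a chain *of* the globule whose own concentration it feels, so its first
monomer is anchored at the field center and the chain radiates across the
density gradient; sampling free chains uniformly over the box
(`anchor="uniform"`) dilutes the per-layer signal with detached chains that
feel no gradient.  Reported: per-position bond probability (its mean equals
the imposed composition exactly), per-shell bond fraction with batch
errors, and the block-size frequency f = f_HB/(f_HB + f_noHB).

## Branched growth

From the third placed monomer on, each newly placed monomer becomes a
branch point with probability θ and is assigned f child branches (default
f = 2, matching branch points drawn with two outgoing bonds).  A branch
point's children are placed consecutively — later siblings see earlier
siblings' sites as occupied — then each child's subtree is grown
depth-first until the monomer budget N is reached.  Each placement draws
its site first and its branching state second; with θ = 0 the topology is
exactly linear and distributionally identical to the linear grower.  A
branch point is bookkept as "the draw fired" even when the budget truncates
its children, which makes the expected branch-point count exactly
θ·(placements − 2) — the oracle used in the tests.  Field coupling is by
Boltzmann-weighting the grown ensemble (e.g. hydrophobic monomers in a
globule's density/solvent stack), under which the branch-point distribution
follows the monomer density distribution.

## Problem sizes and defaults

Scans default to 10⁵ samples per sequence (design orderings such as
alternating-vs-diblock resolve in seconds); quantitative profile numbers in
the tests and the acceptance script use 10⁶–2·10⁶ samples, where the
N = 24 diblock barrier is converged to well under 0.1 k_BT of statistical
error.  The synthetic scenarios the tests rely on (5³ boxes with a
1+1-layer membrane for enumeration oracles, thin-slab toy scans for CLI
checks) exercise every code path of the production geometries at reduced
scale; what they do not probe is behavior at chain lengths or densities
where plain Rosenbluth sampling degrades (N ≳ 50, dense melts), nor any
feedback of the chain on the fields.

## Known limitations

* Mean-field, frozen fields: no inter-chain correlations, no
  self-consistent field loop, no field response to adsorbed chains.
* Plain Rosenbluth sampling: adequate for N ≤ 24 in these fields; longer
  or denser systems would need enrichment methods (out of scope).
* The Kramers escape time assumes one-dimensional diffusion over F(z) with
  a position- and length-independent diffusion constant.
* On-lattice only; 26-neighbor contact counting ties the energy scale to
  this lattice's coordination number.
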