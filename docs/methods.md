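# Methods

Mathematical definitions, default parameters, and numerical design choices.
All quantities are dimensionless; "steps" are discrete Markov-chain steps.

## 1. From contacts to a Markov State Model

For one chromosome binned at resolution `r` (default 50 kbp), let `f_ij` be
the (smoothed) contact count between loci `i` and `j`.

- **Smoothing.** A single isotropic 2D Gaussian convolution with
  `sigma = 200 kbp` (4 bins at 50 kbp), truncated at 4 sigma, zero-padded.
  Smoothed counts are symmetrized exactly. Loci with zero total contacts
  (centromeres, unmappable bins) are removed before any energy is taken and
  mapped back afterwards via a locus mask.
- **Pseudo-energies.** `E_ij = -ln f_ij`; zero-count pairs and the diagonal
  carry infinite energy (no flux).
- **MSM at inverse temperature beta.** Maxwell–Boltzmann flux
  `pi_ij(beta) = exp(-beta E_ij) / Z(beta)` with `Z` summed over ordered
  off-diagonal pairs; stationary weights `mu_i = sum_j pi_ij`; transitions
  `p_ij = pi_ij / mu_i`. The chain is reversible by construction
  (`mu_i p_ij = mu_j p_ji`).

Numerics: the flux is computed in log-space with a max shift so that large
`beta` cannot underflow the dominant contacts; a disconnected positive-flux
graph raises an error (first-passage times would diverge).

**Annealing-parameter selection.** Integer candidates (default 1..12) are
scanned from the largest down; the first `beta` for which the MSM builds,
the flux graph is connected, and every mean-first-passage solve passes a
residual and positivity screen is selected.

## 2. Kinetics

- **MFPT.** For each target `j` the first-step system
  `tau_ij = 1 + sum_{k != j} p_ik tau_kj` is solved densely with row/column
  `j` removed. LU solves are backward stable, so the relative residual of
  each column is checked against `1e-6`; non-finite or non-positive times
  are rejected. (A fundamental-matrix shortcut with a single factorization
  was tried and rejected: at `beta = 10` on the toy chain its forward error
  exceeds the residual tolerance, while the per-column solves stay at
  machine-level residual.)
- **MRT.** `tau_i = 1 + sum_k p_ik tau_ki`, equal to `1 / mu_i` by Kac's
  formula — used as a cross-check, not as the implementation. On strongly
  annealed chains MFPTs reach ~1e12 steps, so the identity holds to
  ~`condition x eps` (~1e-5), not machine precision; on ordinary chains it
  holds to ~1e-14.
- **Pairwise committor.** `Gamma_ij = tau_i / (tau_ij + tau_ji)` in (0, 1]:
  the probability that a walker leaving `i` hits `j` before returning to
  `i`.

## 3. Metastability and hierarchy

For a hub set `M` (|M| = n ≥ 2):

```
rho_M = max_{i in M} max_{j in M \ {i}} Gamma_ij
        ----------------------------------------
        min_{i not in M} max_{j in M} Gamma_ij
```

**Optimization per size n (default n = 2..50):**

1. *Seed pair:* `a = argmax_i mu_i`, `b = argmin_i rho_{a,i}`.
2. *Metropolis Monte Carlo* (default 500 iterations, temperature
   `T_MC = 0.05`): each iteration picks one of two moves with equal
   probability — replace a random hub `a` by its strongest committor partner
   `argmax_i Gamma_ai`, or replace a random hub by a uniformly random
   non-hub locus. Duplicate-producing draws are redrawn (up to 20 times).
   A trial set is accepted when `Delta rho <= 0`, else with probability
   `exp(-Delta rho / T_MC)`. The best set ever visited is returned.
3. *Greedy growth:* size n+1 starts from the size-n optimum extended by the
   locus minimizing `rho` of the union.

Per-size RNG streams are spawned deterministically from one seed, so the
whole profile is reproducible.

**Hierarchy detection.** Strict local minima of `rho(n)` (plateaus count
once, at their smallest n; the last point never counts) with
`rho < 0.8` qualify. The trivial n = 2 level is dropped unless requested; a
greedy ascending pass enforces the doubling rule `n_k >= 2 n_{k-1}`; for
the largest chromosomes (chr1, chr2 by default) the first qualifying
minimum is skipped as too coarse.

## 4. Partitions and comparison

- **Committors.** For hubs `M`, `q_a(i)` solves the harmonic system on
  non-hub loci with boundary values `q_a(a) = 1`, `q_a(b) = 0` (one LU
  factorization shared across hubs). The committors form a partition of
  unity; the argmax over hubs gives hard partitions (ties to the lowest
  genomic hub index).
- **NMI.** Per chromosome, with joint frequencies `nu_AB` of the two
  assignments, `MI = sum nu_AB ln(nu_AB / nu_A nu_B)` and
  `NMI = 2 MI / (H1 + H2)` (identical schemes score 1). The literal
  `1/(H1+H2)` normalization is available as `variant="literal"`.
- **Random-boundary baseline.** For a given scheme, each sample redraws, per
  chromosome, two schemes with the same partition count but uniformly random
  distinct internal boundaries; per-chromosome NMIs are averaged over
  chromosomes and samples. On a genome-scale scheme with 539 partitions
  this chance-agreement level is ~0.77, reflecting that two contiguous
  partitions of matching cardinality always share substantial information.
- **RMI.** `RMI = (NMI - 0.77) / (1 - 0.77)` rescales NMI so 0 is chance
  agreement of contiguous schemes and 1 is identity.

## 5. Interactions between partitions

- **Soft (single chromosome):** `F_ab = sum_i q_a(i) pi_ib` over hubs `b`;
  column sums of the raw matrix equal the hub stationary weights
  (partition-of-unity check); reported symmetrized.
- **Hard (genome):** `F_AB = theta_A^T Pi theta_B` with indicator vectors
  `theta` and the genome flux `Pi` (counts normalized over ordered
  off-diagonal pairs). Genome-wide committors are never computed.
- **Layers.** Unordered pairs ranked by `F` descending form the scaffold
  (default: strongest 2000 pairs, ties at the cutoff included) and
  percentile bands 1.35/1.5/1.7/2.0% (layers 1..3); the rest is "below".
  The major cluster is the largest connected component of the
  scaffold-plus-layer-1 graph.
- **Affinity.** `C_AB = P(A and B) / (P(A) P(B))` with `P(A and B)` the
  fraction of inter-partition counts on the pair and
  `P(A) = sum_{B != A} P(A and B)` (so `sum_A P(A) = 1` exactly). A
  two-partition system gives `C = 2` exactly; rank-one (product-structured)
  counts give `C ~ 1`. Scale-invariant in the counts.

## 6. Epigenomic overlays

Signal tracks (bedGraph) are aggregated to length-weighted mean densities
per partition (uncovered bases count 0); densities are Z-scored across
partitions with partition-length weights. Giemsa cytoband composition
classifies a partition as euchromatic (EC) when > 80% of its length is
gneg/gpos25, heterochromatic (HC) when > 80% is gpos50/75/100, otherwise
mixed. Factor enrichment on partition pairs regresses
`ln(d_A d_B)` on `ln F_AB` over pairs of a given class combination
(Pearson r, two-sided p); constant inputs report slope 0, r 0, p 1 by
definition.

## 7. The toy chromosome

A 500-locus chain carries intrinsic energies shaped as three nested levels
of wells: branching (2, 3, 3) — 18 leaf wells in contiguous equal blocks —
with barrier heights 2.0 / 1.25 / 0.5 set by the highest hierarchy level
separating adjacent wells. Pair energies add a power-law contact decay:

```
E_ij = (E_i + E_j)/2 + alpha * ln|i - j|,    alpha = 1.5,
```

and the toy MSM is the Boltzmann-flux MSM of these pair energies (beta = 10
by default in the analyses).

**Well-depth disorder.** Well floors receive seeded uniform offsets in
`[0, 0.5)` — up to the smallest barrier height, so the disorder can never
override the level structure. Barrier tops sit at
`max(adjacent floors) + level height`, and the floor locus is pinned
exactly on-grid, so the profile has exactly 17 strict internal maxima whose
prominence is exactly the height of their hierarchy level. The disorder is
essential, not cosmetic: with all wells equally deep, intermediate hub-set
sizes are massively degenerate (many covers of identical wells reach
`rho ~ 0.5`, far below the 0.8 threshold), so any finite-budget optimizer
scatters spurious sub-threshold minima across the profile. Unequal depths
remove the degeneracy, and the `rho(n)` profile shows three clean minima at
n = 2, 6, 18 — the planted hierarchy.

Ground-truth basin labels at every level ship with the profile, enabling
exact fidelity measurements (fraction of loci whose partition's majority
basin matches their own; ≥ 98% at all three levels at `beta = 10`).

## 8. Reproducibility

Every stochastic component takes an explicit seed; per-size and
per-replicate streams are spawned from `numpy.random.SeedSequence`.
Pipeline runs write a manifest of SHA-256 content hashes; reruns under a
fixed seed are byte-identical.
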