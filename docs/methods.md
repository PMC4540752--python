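# Methods

## Model

`dtwalk` treats drug–target prediction as proximity ranking on an
undirected heterogeneous network with two node types.  The three data
layers are a drug–drug similarity matrix `S_d`, a target–target
similarity matrix `S_t`, and the binary interaction incidence `A`
(drugs × targets).  Each similarity layer is itself a convex blend of a
*feature* similarity and a *topology* similarity:

* drugs — Tanimoto coefficient on binary chemical fingerprints (`C_s`)
  blended with the Jaccard coefficient of shared targets
  (`C_s^n(i, j) = M(i, j)/(M(i, i) + M(j, j) − M(i, j))`, `M = A Aᵀ`);
* targets — Smith–Waterman local-alignment scores normalized to a
  unit-diagonal kernel, `T_s = SW(g, g′)/√(SW(g, g) SW(g′, g′))`, blended
  with the Jaccard coefficient of shared drugs (`M = Aᵀ A`).

Every similarity layer is validated on construction: symmetric within
1e-12, values in [0, 1], diagonal exactly 1.

### Transition matrix

Nodes carrying at least one interaction link are bridge nodes.  A walker
at a bridge drug `d` crosses to a linked target with total probability
`λ` (split evenly over its links, `W_DT(d, t) = λ A(d, t)/deg d`) and
moves within the drug layer with total probability `1 − λ`, distributed
proportionally to similarity (`W_DD(d, d′) = (1 − λ) S_d(d, d′)/Σ S_d(d, ·)`).
Symmetric rules govern targets.  Three deliberate choices make `W`
row-stochastic in every case:

* **no self-loops** — similarity diagonals are zeroed before row
  normalization, since a self-similarity of 1 would dominate every row
  and slow mixing;
* **non-bridge rows renormalize to full weight** — a node without links
  distributes all of its mass within its own layer (the jumping
  probability applies only at bridge nodes);
* **degenerate rows self-loop** — a node with neither links nor
  within-layer similarity mass keeps its layer share on a self-loop, so
  no probability leaks.

The printed two-by-two block form of `W` uses `W_TD` (target→drug) and
`W_DT` (drug→target) in the two off-diagonal positions; anything else
could not be row-stochastic.

### Walk and seeds

The walk iterates `p_{t+1} = (1 − c) Wᵀ p_t + c p_0` until the Euclidean
norm of the change is below `tol` (for a vector the Frobenius norm is the
Euclidean norm).  The fixed point equals
`c (I − (1 − c) Wᵀ)⁻¹ p_0`; the iteration is preferred at scale and is
cross-checked against the direct solve in the test suite.

Seeds are the query drug plus its directly linked targets.  The seed
indicators are normalized to unit mass *within each class* before the
η-split, so `p_0 = [(1 − η) u_0; η v_0]` is a probability vector (the
fixed point is scale-invariant, but probability semantics and the mass
conservation checks require unit mass).  If one seed class is empty —
notably a drug with no known target — the entire restart mass goes to the
other class regardless of η, which is what makes orphan drugs queryable.

### Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `c` | 0.3 | restart probability; rankings are known to be insensitive to it, the conventional value is kept |
| `η` | 0.01 | restart share on the drug seed vs its targets; small-but-nonzero is the benchmark optimum |
| `λ` | 0.5 | bridge-node jumping probability; no principled prior favors either layer, so cross/within are balanced — exposed as a first-class configurable |
| `w_d`, `w_t` | 0.5 | feature/topology blend weights; performance degrades at the extremes 0 and 1 and peaks at even weighting |
| `tol` | 1e-10 | convergence threshold on ‖p_{t+1} − p_t‖₂ |
| SW scoring | BLOSUM62, gap open 10, extend 0.5 | community-standard local-alignment defaults; the unit normalization makes the kernel only weakly sensitive to the absolute scale |
| BEDROC α | 20 | the literature-standard early-recognition weighting |
| EF window | 0.1 | matches reporting partial AUC on the top decile |

External similarity matrices (for example 3D shape + pharmacophore-color
"combo" scores, which live on (0, 2]) are accepted as precomputed layers
and rescaled linearly from their declared range to [0, 1], since blending
and row normalization require a common scale.

## Evaluation protocols

*Single link per drug*: every drug with ≥ 1 target loses one uniformly
chosen link (seeded RNG — the choice rule is a package decision; uniform
is unbiased and reproducible); the walk re-runs with the drug's remaining
seeds and the hidden target's rank is recorded.  *Fixed count*: `n`
links are removed simultaneously from drugs with degree ≥ 3, over
repeated resamplings.  In both protocols the shared-neighbor similarity
layers are **recomputed from the perturbed incidence** before the walk;
anything else would leak the hidden link back in through `C_s^n`/`T_s^n`.

Metrics are computed on pooled records (one ranked outcome per hidden
link).  Ranks are 1-based.  Conventions, with `r` the hit's rank among
`n` candidates:

* recovered fraction at N — share of records with `r ≤ N`;
* AUC — pooled Mann–Whitney statistic: Σ(n − r) / Σ(n − 1) over records
  (the probability that the hidden target outranks a random non-hit);
* AUAC — `1 − mean(r/n)`, the area under the accumulation curve;
* partial AUC (top fraction f) — per record `max(0, f − (r−1)/(n−1))/f`,
  averaged; a uniformly random ranking scores `f/2`, not 0.5;
* BEDROC(α) — RIE on relative ranks `x = (r−1)/(n−1)` rescaled between
  its closed-form extremes, so all-hits-first gives exactly 1 and
  all-hits-last exactly 0; a uniform ranking gives ≈ 0.05 at α = 20;
* EF(f) — hit rate within the top `f` of each list divided by `f`;
  expectation 1 under random ranking, maximum `1/f`.

Records with a single candidate are excluded from rank-normalized metrics
with a warning (their relative rank is undefined).

Two baselines: a **degree-preserving randomized network** (bipartite
pair-swap rewiring of `A` plus symmetric permutation of the similarity
off-diagonals, then the identical pipeline) and a **sequence-similarity
ranking** (each candidate scored by its maximum `T_s` to the drug's known
targets — no diffusion).

## Synthetic benchmark worlds

The generator plants recoverable structure: drugs and targets are
partitioned into matched clusters; each cluster owns a template
fingerprint (166 bits wide, 30 cluster bits, MACCS-like) and a template
sequence (120 residues); members flip 10 random bits and substitute 10%
of residues (uniform substitutions, no indels — local alignment is still
exercised, and indel realism adds nothing to correctness testing).
Links are Bernoulli with probability 0.3 within a cluster and 0.01
across; 20% of links are withheld as ground truth, never removing a
drug's last link.  Defaults: 60 drugs, 60 targets, 4 clusters, seed 7.

What the world does emulate: correlated feature and interaction signal,
cluster-structured similarity, orphan-adjacent drugs, both perturbation
modes.  What it does not: the heavy-tailed degree distribution of real
drug–target data, cross-species target families, assay noise, and
realistic fingerprint bit correlations.  Passing tests on these worlds
therefore demonstrates the machinery recovers planted signal under
controlled conditions, not field performance on curated databases.

### Problem sizes used in the shipped checks

The test suite and the acceptance script run the default 60 × 60 world
(≈ 220 kept links, ≈ 56 held out), 5 resamplings per fixed-count removal
setting at 10/30/50% of eligible links, and 50 random ≤ 30-node networks
for the closed-form cross-check — sizes at which every quantity is
recomputed from scratch in seconds while the planted signal is already
unambiguous.

A known quantitative ceiling of this scale: with only ~56 candidate
targets per query, a random ranking already places ~18% of hidden
targets in the top 10, and a cluster of 15 targets cannot fit entirely
inside a top-10 window; the RWR-to-baseline recovery ratio at top 10 is
therefore bounded near 4–5 on these worlds even for a perfect method,
whereas on thousand-target networks the same ratio is effectively
unbounded.  The suite asserts strict dominance of RWR over the baseline
on AUC, BEDROC and recovered fraction, plus the degradation trend as the
number of simultaneously removed links grows.

## Numerical and degenerate-input choices

* Ties in any ranking break lexicographically on target id — rankings
  are bit-reproducible.
* A drug with zero fingerprint bits (or a node with no interaction
  neighbors) gets similarity 0 off-diagonal and 1 on the diagonal with a
  logged warning; such nodes remain in the network and are reachable
  through the other layers.
* A sequence whose self-alignment score is not positive cannot be
  normalized and is rejected by id.
* All indices are 0-based internally and 1-based in rank reports.
* Id matching is case-sensitive exact string comparison; identifier
  mapping between databases is out of scope.

## Limitations

* Edges are binary: quantitative bioactivity values are not modelled.
* Dense similarity layers: memory is quadratic in the larger node set;
  an optional similarity cutoff sparsifies but is off by default, as it
  is unknown whether thresholding helps.
* Reverse queries (ranking drugs for a target) fall out of the symmetric
  data model but are not benchmarked.
* The fingerprint adapter covers MACCS and Morgan/ECFP-style circular
  fingerprints via rdkit; 3D shape similarity must be supplied as a
  precomputed external layer.
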