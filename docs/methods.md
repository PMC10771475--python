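# Methods

This document records the model formulation, the numerical choices made in
this implementation, the scope of the synthetic fixture generator, and known
limitations.

## Problem statement

Given an atom-mapped gas-phase reaction `reactants>>products`, generate an
ensemble of 3D transition-state (TS) geometries `C ∈ R^{N×3}` consistent
with the reaction. The model is a denoising diffusion probabilistic model
conditioned on the 2D *condensed reaction graph*; no 3D information about
reactants or products is used at inference time.

## Condensed reaction graph

Both sides of the reaction are parsed (RDKit) into molecular graphs over the
same atom set, aligned by the atom mapping; node `k` holds map id `k+1`.
Hydrogens are explicit throughout; implicit hydrogens are expanded and
auto-mapped deterministically (per heavy atom in map order).

- **Node features** (per side, concatenated reactant‖product, 13+13=26):
  one-hot element (H, C, N, O), one-hot hybridization (SP/SP2/SP3/other),
  and scalars for total valence, formal charge, aromaticity, ring
  membership, and chirality parity.
- **Edge set**: the union of both sides' 3-hop extensions — all atom pairs
  within graph distance 3 over covalent bonds, computed per connected
  component.
- **Edge features** (per side, 8+8=16): one-hot bond type (single, double,
  triple, aromatic, *none* for extended non-bonded pairs) plus a one-hot of
  the graph distance (1–3). A pair absent from one side carries that side's
  all-zero vector, which is thereby reserved as the "not on this side"
  (and, in the geometric graph, "radius edge") symbol.

Training-set augmentation adds the reverse reaction of every record (the
reactant/product feature halves swapped); the reference geometry is shared,
since the TS of the reverse reaction is the same saddle point.

## Diffusion process

Forward process: `q(C_t | C_0) = N(√ᾱ_t C_0, (1-ᾱ_t) I)` with
`α_t = 1-β_t`, `ᾱ_t = Π_{s≤t} α_s`, `t = 1..T`. `C_0` is zero-centered
(translation gauge fix). Default schedule: sigmoid β curve, `T = 5000`,
`β_1 = 1e-7`, `β_T = 4e-3`. The terminal marginal must be statistically
indistinguishable from the standard-normal prior; the default satisfies
`ᾱ_T < 1e-4`, and the check is opt-in (`prior_tol`) so that deliberately
short toy schedules remain constructible. Desk-scale studies use `T = 200`,
`β ∈ [1e-5, 5e-2]` (also `ᾱ_T ≈ 6e-3`; adequate for the toy geometries,
whose scale is ~1 Å).

Reverse process: `p(C_{t-1} | C_t, G) = N(μ_θ, σ_t² I)` with

```
μ_θ = ( C_t − (β_t / √(1−ᾱ_t)) ε_θ(C_t, G, t) ) / √α_t
```

`σ_t² = β_t` by default (posterior variance available as an option). The
final step `t = 1` adds no noise. Model ensembles average `ε_θ` at every
step. Each sampling round runs the full T-step chain from fresh
`C_T ~ N(0, I)`.

## Score network

The network predicts the score *in distance coordinates*: one scalar
`s_ij` per edge of the **geometric graph** — the reaction-graph edges (kept
at any distance) plus radius edges (non-graph pairs currently closer than a
10 Å cutoff, carrying the all-zero edge feature), rebuilt from the current
positions at every denoising step. Positions enter only through interatomic
distances, so `s_ij` is invariant under rigid motions and reflections. The
chain rule projects edge scores to atoms:

```
ε_θ[i] = Σ_{j : (i,j) ∈ E}  s_ij (x_i − x_j) / d_ij
```

which is translation-invariant, rotation-equivariant, and sums to zero over
atoms. Verified numerically to ~1e-15 over random rigid motions, including
improper ones.

Architecture (a SchNet variant): node features ‖ sinusoidal time embedding
→ linear embedding; `L` interaction blocks

```
m_ij = MLP2(h_j) ⊙ ( W_rbf rbf(d_ij) ⊙ π_edge(f_ij) )
h_i ← MLP1( MLP2(h_i) + Σ_j m_ij )
```

with shifted-softplus activations and Gaussian radial basis functions; a
per-edge head on `[h_i ‖ h_j ‖ rbf(d_ij) ‖ π_edge(f_ij)]`, averaged over
both edge orientations so the score is symmetric in (i, j).

## Training objective

The loss is the standard noise-matching objective with unit KL
coefficients: `|| ε − ε_θ(C_t, G, t) ||²` summed over xyz and averaged over
atoms, with `ε` the standardized Cartesian noise drawn in the forward
sample and `ε_θ` the chain-rule projection of the per-edge scores.

A tempting alternative is to form a per-edge target in distance
coordinates, `(d_t − √ᾱ_t d_0)/√(1−ᾱ_t)`, project *it* through the chain
rule, and regress the projected prediction on the projected target. The two
objectives are **not** equivalent: the projection sums one contribution per
incident extended edge into each atom, so the projected distance-space
target has per-atom magnitude roughly twice the Cartesian `ε` on these
graphs. A reverse process driven by that inflated field is over-contractive
and collapses minor conformational modes — measured directly on the
two-mode toy fixtures, where the distance-target variant generated only the
dominant mode while an exact mixture-score oracle pushed through the same
sampler was cleanly bimodal. This package therefore regresses the projected
output onto the Cartesian noise; the per-edge distance target remains
available as a standalone primitive (`score_target_distance`).

Optimization: plain Adam in NumPy. Batches are disjoint unions of the
per-record geometric graphs (index offsets); each record draws its own
uniform `t`. Every training step derives its RNG from a per-step child seed
(`SeedSequence(entropy=seed, spawn_key=(step,))`), which makes interrupted
and resumed runs bit-identical to uninterrupted ones.

## Evaluation metrics

The base metric is the mean absolute error of interatomic distances
(D-MAE), `2/(N(N−1)) Σ_{i<j} |d_ij − d'_ij|`, blind to rigid motions and
reflections. The *aligned* variant minimizes over the automorphisms of the
condensed reaction graph — relabelings preserving both sides' bonds and all
atom features — computed on the 1-hop bond-skeleton union with node labels =
full node features and edge labels = (reactant, product) bond-type pairs.
Exhaustive minimization over all feature-compatible permutations agrees to
machine precision on every tested case.

Ensemble scores over generated set S_gen and reference set S_ref:

- **COV(δ)**: percentage of references with some sample at aligned D-MAE
  < δ (non-decreasing in δ and in |S_gen|).
- **MAT**: mean over references of the minimum aligned D-MAE
  (non-increasing in |S_gen|).
- **Deduplication**: single-linkage clustering at an aligned D-MAE
  threshold of 0.01 Å (connected components, order-independent).

## Toy fixture generator: scope

Four templated bond-cleavage/elimination reactions over C, H, O, N
(6–8 atoms): methanol H2 elimination, ethane C–C homolysis, methylamine
C–N cleavage, methanol C–O cleavage. "Transition-state" geometries are
built internally from idealized bond lengths/angles via z-matrix (NeRF)
construction — no chemistry engine, bit-reproducible, text-only. Each
template owns 2–3 conformational modes (early/late stretches of the
breaking bond, torsional variants) kept ≥ 0.3 Å apart in aligned D-MAE;
per-record reference noise is 0.02 Å per coordinate, far below the mode
separation. The generator mimics the real training signal (one reference
geometry per reaction) but makes no claim of chemical accuracy; it exists
to exercise the pipeline and metrics deterministically.

The published curated database split is represented arithmetically: 11,959
reactions partition into 9,566 / 1,196 / 1,197 (train/valid/test). These
sizes are pinned explicitly (`rule="published"`) because no standard rounding
of an 8:1:1 ratio reproduces them. Reverse augmentation doubles the
training partition to 19,132; 8 sampling rounds over the test partition
yield 9,576 geometries.

## Numerical choices

- Pure NumPy reverse-mode autodiff engine (`tsdiff.autodiff`): the target
  environment has no GPU deep-learning framework, and desk-scale graphs
  (tens of atoms, hundreds of edges) do not need one. Gradients are
  verified against central-difference oracles.
- Float64 throughout; XYZ files round-trip at 1e-6 Å.
- Checkpoints are single `.npz` files carrying parameters plus a hashed
  config; loading verifies the hash.
- Geometric-graph construction rejects coincident atoms (zero-length
  edges) instead of silently regularizing.

## Limitations

- Element vocabulary is H/C/N/O (extendable via `ELEMENTS`); other
  elements fall outside the one-hot block.
- The score network capacity and schedule defaults are tuned for the toy
  regime in the studies; the full-scale defaults (hidden 256, 7 layers,
  T = 5000) are provided but not trained here — CPU-only training at that
  scale is impractical.
- No graph-isomorphism-hardened automorphism search: `networkx`'s
  GraphMatcher is exponential in the worst case, fine at ≤ tens of atoms.
- The toy geometries are idealized, not stationary points of any potential;
  quantitative claims about real TS databases are out of scope.
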