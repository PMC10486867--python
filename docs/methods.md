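# Methods

## The model

`scgem` is a finite-truncation nested topic model for UMI count matrices.
A preset tree (branching list, e.g. `[5, 4, 3]`) defines K GEM nodes, each
carrying a gene distribution β_k on the simplex with a symmetric Dirichlet
prior of weight η. Conceptually the tree is the truncation of a nested
hierarchical Dirichlet process: a global DP (concentration α) provides the
shared atoms, and each cell draws its own distribution over them with
cell-level concentration τ via stick-breaking, walking the tree from the top
and descending a level with switching probability γ. Because the tree is
explicitly preset and finite — the practical regime this package targets —
the global-level stick-breaking collapses into the fixed node set, so α does
not appear in the fitting updates (it is kept on the model and used by the
CRP predictive utility). Counts are multinomial draws from the per-cell
mixture Σ_k θ_dk β_kg.

Per-cell loadings θ_d over the K nodes are reparametrized **exactly** by
local tree decisions:

* a stop-vs-descend probability σ_dk at every internal node, and
* a sibling-choice distribution ψ_d over every sibling group
  (top-level nodes form a group under a virtual root).

θ_dk is the product of the sibling choices along the path to k, the
continuation probabilities (1 − σ) of its ancestors, and σ_k (leaves always
stop). This map is a bijection between the θ simplex and the product of
local simplices, so optimizing the local parameters is optimizing θ — no
structure is lost, and the "active subtree" of a cell is automatically
closed under the parent relation because mass can only reach a node through
its ancestors.

## Priors and the role of γ and τ

Local decisions carry conjugate-style pseudo-count penalties:

* stop-vs-descend at an internal node: `s0·(1−γ)` pseudo-tokens on stopping
  and `s0·γ` on descending, with switch strength `s0` (default 10 pseudo
  tokens per internal node). Lower γ therefore pulls per-cell mass toward
  the upper levels — the conservative "shallow" behaviour (γ = 0.5); the
  default γ = 0.75 encourages the walk toward the leaves.
* sibling choice: a size-biased prior τ·w_c where w_c are the expected
  truncated stick-breaking weights with concentration τ, ordered by node id
  (the last sibling absorbs the remainder). This bakes the stick-breaking
  size bias of the nested construction into the finite model.

A design note on the switch variable: rather than keeping a Beta-form
variational posterior per cell, we use MAP point estimates of σ and ψ
(closed-form pseudo-count updates). The decisive advantage is exactness:
with point-mass local posteriors, one-batch training is plain EM on the
penalized objective

    J = Σ_dg C_dg log Σ_k θ_dk β_kg
        + Σ_d Σ_internal [s0(1−γ) log σ + s0γ log(1−σ)]
        + Σ_d Σ_groups Σ_c τ w_c log ψ_c
        + η Σ_kg log β_kg

and every epoch provably does not decrease J — the monotonicity contract the
`FitTrace` carries (and the tests check to 1e-6 relative on random
corpora). A distributional posterior for a single Bernoulli-like switch adds
an entropy term of negligible practical effect here while voiding that exact
guarantee.

## Training

**E-step** (vectorized over the sparse count pattern): token
responsibilities n_dk = θ_dk Σ_g C_dg β_kg / (θβ)_dg. **M-step**: subtree
masses m_dk aggregate n bottom-up; then

* σ_dk = (n_dk + s0(1−γ)) / (m_dk + s0),
* ψ_dc ∝ m_dc + τ w_c within each sibling group,
* β_kg ∝ Σ_d n_dgk + η (one-batch), computed from the same E-step.

Mini-batch mode replaces the global β update with a stochastic
interpolation β ← (1−ρ)β + ρ·β̂(batch) at constant learning rate ρ
(default 0.01; an optional Robbins–Monro decay flag exists but constant is
the default), over a seeded shuffle per epoch, with a few inner local-EM
sweeps per batch (default 8). Convergence is declared when the relative
epoch-objective change falls below `conv_tol` (default 1e-4).

Fold-in inference (`infer_loadings`) runs only the per-cell updates with β
frozen, to a θ change below 1e-8 or 200 sweeps; it is deterministic, and
cells sharing no genes with the model get a uniform top-level θ and a
logged warning. Warm starts (`warm_start`) transfer a pretrained β onto a
new vocabulary: shared genes keep their weights, unseen genes enter at η
mass, rows renormalize.

## Tree initialization

Algorithm: normalize each cell's counts to proportions; cluster a seeded
subsample into the top-level nodes with L1 KMeans (k-medians: centroid =
element-wise median, the exact L1 minimizer; k-means++-style L1 seeding;
8 restarts keeping the lowest total L1 cost; empty clusters re-seeded from
the worst-fit row); then, per level, residualize each cell against its
assigned parent centroid and cluster the residuals into the children.

The "break the information" residual is the single most consequential
interpretation in the codebase: with the centroid renormalized to Θ̂ and
overlap coefficient c = Σ_g min(x_g, Θ̂_g), the residual is
max(0, x − c·Θ̂), renormalized. It removes exactly the proportion mass the
centroid can explain, stays non-negative, returns x untouched when the
centroid lives on disjoint genes, and flags fully-explained cells. Levels
are processed in a single top-down pass by default (`sweeps` re-runs the
pass; residualization makes repeated sweeps ill-defined as a fixed point,
so 1 is the recommended reading). Parents with fewer cells than children
seed their children from a noise-perturbed copy of the parent centroid
(logged). Final `init_beta` adds smoothing 1e-6 and renormalizes so
downstream logarithms are finite.

## Synthetic data

Two generators, both pure functions of parameters + seed:

* **Unstructured counts** (`simulate_splatter_like`): gene means
  ~ Gamma(0.6, rate 0.3), library sizes ~ LogNormal(7.6, 0.35) — median
  ≈ 2000 UMIs/cell, typical of 10x data — and C_dg ~ Poisson(L_d m_g/Σm).
  This is the gamma-mean × log-normal-library × Poisson core of
  splatter-style simulation; dropout beyond Poisson zeros, batch effects,
  and DE factors are deliberately not modelled.
* **Planted-tree corpora** (`simulate_planted_tree`): ground-truth β built
  by `make_beta_true` — every node owns a disjoint block of specific genes
  with a sparse Dirichlet(0.5) profile, children mix `parent_share` of the
  parent profile with their own block — and cells walk the tree exactly as
  the model assumes (stick-breaking siblings at τ_true, descent at
  γ_true), spread θ over the path by stick-breaking, and draw Poisson
  counts from L_d·(θβ).

Passing recovery tests on planted data shows the inference machinery
recovers the structure it assumes; it does not certify behaviour under
real-data violations (batch effects, ambient RNA, bursty over-dispersion
beyond the library-size log-normal, genes shared across unrelated
programs).

## Evaluation metrics

* Predictive log-likelihood and perplexity exactly as defined above;
  uniform β gives perplexity = vocabulary size, the natural ceiling for a
  proper per-cell mixture (floor 1).
* PMI coherence: presence = count > 0 per cell; p(g) and p(g_i, g_j) are
  cell fractions on a reference corpus (default: the training corpus;
  passable explicitly), smoothed by 1e-12; the score is the raw **sum**
  over all C(top_n, 2) pairs of the GEM's top-n genes (default 50), so
  comparisons require equal top_n.
* Cosine similarity on vectors, or on gene sets embedded as binary
  indicators over the union vocabulary (sets of size 150 sharing 75 genes
  score 0.5); the GEM×marker and GEM×GEM similarity matrices use each
  GEM's top 150 genes by default.
* Gene sets export as standard GMT lines (`GEM_<id>`, level tag, genes).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| γ (`gamma_switch`) | 0.75 | probability of descending a level; 0.5 = shallow preset |
| τ (`tau`) | 1.0 | cell-level stick-breaking concentration (sibling size bias) |
| η (`eta`) | 0.01 | Dirichlet weight per gene on β rows |
| α (`alpha`) | 1.0 | global DP concentration (CRP utility; inert in finite fitting) |
| `switch_strength` | 10 | pseudo-tokens of the γ prior per internal node |
| `learning_rate` | 0.01 | mini-batch interpolation step (constant) |
| `conv_tol` | 1e-4 | relative objective change declaring convergence |
| `batch_size` | 512 | mini-batch size |
| QC | 200 / 2500 / 5% | detected-gene bounds and mito-fraction cutoff (strict removal conditions, closed kept interval) |

## Numerical choices and degenerate inputs

All β and θ rows are renormalized simplex rows (checked at 1e-9); η and the
init smoothing keep every log finite. Ties in top-gene ranking resolve by
input gene order (stable sort); k-medians assignment ties go to the lowest
centroid index. All-zero cells are flagged through normalization and get
uniform top-level θ at fold-in. Duplicate gene names are deterministically
suffixed `.1`, `.2`, … at read time. Gene-set mismatches between counts and
a model are intersected with a warning; full disjointness is an error.

## Harness problem sizes

The test suite and acceptance script run the pipeline at desk scale, chosen
to exercise every code path with stable statistics: recovery on three
planted corpora of 2000 cells × 1500 genes over a `[3,2,2]` tree
(21 GEMs); perplexity curves over nested training sizes 500–4000 with a
500-cell held-out set, fitted from a shared initialization so size
comparisons are paired; warm-vs-cold comparisons on 1500-cell corpora
drawn from one planted model. Mean best-match recovery lands just above
0.8: the residual gap is concentrated in planted leaves that receive only
~10–20 cells of expected mass under the stick-breaking size bias, which no
estimator can pin down from that little data.

## Known limitations

The tree is fixed a priori — no growth, pruning, or untruncated
nonparametrics. MAP local parameters understate per-cell uncertainty in θ.
Mini-batch training has no monotonicity guarantee (only the one-batch
objective is provably non-decreasing). Coherence estimated on the training
corpus is mildly optimistic versus an independent reference. The simulators
do not model batch effects or gene-level over-dispersion beyond the
library-size log-normal, so absolute perplexities on real data will differ
from synthetic ones.
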