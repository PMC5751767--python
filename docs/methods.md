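# Methods

## The similarity model

Drugs are points in a binary descriptor space (presence/absence of
substructure keys, targets, enzymes, …). Locally, such a point cloud behaves
like a linear patch: a drug can be approximated by a convex combination of its
neighbors, and the combination coefficients quantify how much each neighbor
"explains" the drug. For drug *i* with neighbor set `N(X_i)` of size *K*, the
weights solve

    min_w  wᵀ(Gⁱ + λI)w    s.t.  Σw = 1, w ≥ 0,

where `Gⁱ_jk = (X_i − X_j)·(X_i − X_k)` is the Gram matrix of the stacked
difference vectors `D` (`Gⁱ = DDᵀ`; the diagonal is the squared center–neighbor
distance). λ=0 gives LN similarity, λ=1 the regularized RLN form. The rationale
for a *unit* ridge: on the simplex `‖w‖² ≤ 1`, while the reconstruction error
is at most *p* for binary vectors (each coordinate of the reconstruction
residual lies in [−1,1]), so with *p* ≫ 1 the penalty can never dominate the
error term, yet it makes the QP strictly convex. This matters in practice:
whenever two neighbors coincide — or more generally when the ≤ *p*-rank Gram is
singular, the typical case when *K* exceeds the descriptor dimension, as it
always does for association profiles — the λ=0 problem can have no invertible
KKT system and the solver raises a diagnostic pointing at RLN.

### QP solver

No QP library is used; the problem structure (one equality, bound
constraints, PSD Hessian) is narrow enough that a primal active-set method
with an explicit KKT certificate is both faster and easier to audit than a
general solver. Free-set subproblems are solved via the bordered KKT system;
variables that go negative are clamped to zero (all at once while that makes
progress, one at a time otherwise — the conservative mode cannot cycle on a
strictly convex objective), and clamped variables re-enter when their
multiplier `η_i = 2(Qw)_i − ν` goes negative. Termination requires the full
KKT conditions within 1e-10·scale(Q); ill-conditioned equality solves (relative
residual above 1e-8) are reported as singular rather than silently accepted.
Residual negative entries from finite precision are clipped at 0 and the row
renormalized; a clip beyond 1e-6 is treated as a solver failure, preserving the
row-stochastic contract. Tests cross-check the solver against an exhaustive
0.01-step simplex grid (K=3) and scipy's SLSQP on larger instances.

### Conventions the model statement leaves open

* Neighbor metric: Euclidean on the raw binary vectors — the same geometry as
  the QP's squared error. Ties in distance break by ascending drug index
  (stable argsort), making every output a pure function of the input.
* Self-exclusion: a drug is never its own neighbor, hence `diag(W) = 0`;
  including it would make propagation trivially self-reinforcing.
* Out-of-sample drugs search all N training drugs (there is no self to
  exclude); a held-out training row therefore reproduces its in-sample
  similarity row exactly, which is asserted as a consistency test.
* Baseline similarities (Jaccard, cosine, Gauss with bandwidth default 1/p)
  are dense and unnormalized; they exist for graph-quality comparisons, not
  propagation, whose guarantees need row-stochasticity.

## Label propagation

With row-stochastic `W` and absorbing probability α ∈ [0,1), the update
`Y ← αWY + (1−α)Y⁰` is a contraction converging to
`Y′ = (1−α)(I−αW)⁻¹Y⁰`. The closed form is computed as a linear solve, never
an explicit inverse. Both modes are implemented and asserted to agree to 1e-8;
the iterative mode (defaults: tol 1e-9, max 1000 sweeps) exists mainly as an
independent check of the algebra. Every propagated score is a convex
combination of initial labels, so scores stay in [0,1], and any cell with
`Y⁰_ij = 1` retains at least `(1−α)` — the floor used to sanity-check SEAD
predictions. For symmetric `W` the fixed point is also the minimizer of
`α·tr(Yᵀ(I−W)Y) + (1−α)‖Y−Y⁰‖²_F`; since LN/RLN graphs are directed, the test
suite verifies this equivalence on symmetric doubly stochastic instances
(symmetric Sinkhorn scaling) rather than pretending it holds for the
asymmetric case.

New drugs are scored as `Y_new = W_new·Y`. For single-view LNSM, `Y` is read
as the *converged* label matrix `Y′` (the updated labels), a configurable
choice (`transfer="propagated" | "raw"`). For multi-view SMI prediction the
default is the raw `Y⁰`, matching the method's stated formula
`Y_new = (Σθ_k W_new^k)Y⁰`; the propagated variant is available behind the
same flag.

## Multi-view integration

Fixing `Y = Y⁰` in the propagation objective and adding a ridge `δ‖θ‖²`
reduces weight estimation over `Σθ_k W_k` to

    min_θ  α·Cᵀθ + δ‖θ‖²    s.t.  Σθ = 1, θ ≥ 0,
    c_k = tr((Y⁰)ᵀ(I − W_k) Y⁰)  (computed as Σ y·(y − Wy), no N×N product),

with KKT system `2δθ + αC − λe − η = 0`, `eᵀθ = 1`, `η,θ ≥ 0`, `η_iθ_i = 0`.
Sorting costs ascending, the support is the longest prefix satisfying
`2δ + αΣ_{k≤n}(c_k − c_n) ≥ 0` (this is the working form of the support
condition; the equivalent characterization via λ is `λ > αc_n`), on which
`θ_k = (λ − αc_k)/(2δ)` with `λ = (2δ + αΣ_{k≤l}c_k)/l`. The auto rule
`δ = (α/2)Σ_k(c_max − c_k)` is the largest δ that still zeroes the worst view,
and collapses the solution to `θ_k = (c_max − c_k)/Σ_j(c_max − c_j)` — α
cancels, so with auto-δ the weights depend on the costs alone (documented and
tested). Degenerate all-equal costs (including the single-view case) make the
objective symmetric; the implementation returns uniform weights with a
warning, the limit of the general solution as the costs coalesce. Every
returned solution carries its multipliers and is KKT-certified in tests
against an SLSQP minimizer.

## SEAD (LNSM-MSE)

Association profiles `A(i,:)` serve directly as feature vectors; RLN is the
default (profile Grams are always rank-deficient at K ≈ N), with K=800 (capped
at N−1) and α=0.3 as the recommended operating point, versus K=400, α=0.8 for
SEND — propagation on the association graph works best with weaker absorption
because the profiles are themselves the labels. During known-side-effect-wise
cross-validation, held-out positives are zeroed *before* similarity
computation as well as propagation, so no held-out information leaks through
the graph. All-zero profiles are warned about and retained.

## Evaluation conventions

Per-drug ranking metrics (one-error, coverage, ranking loss, average
precision) plus Hamming loss at a threshold, and pooled AUC/AUPR over all
cells (micro; per-drug macro averages are also reported, micro is primary
since the class imbalance is the point of AUPR). Choices the definitions leave
open, fixed here and mirrored by the brute-force test oracles:

* AUC is the tie-averaged Mann–Whitney statistic; AUPR is non-interpolated
  step-curve average precision with tied scores entering as one block.
* Coverage uses average ranks under ties and is un-normalized (0..M−1).
* Ranking loss counts a tied (true, false) pair as half an error; drugs with
  no true or no false labels are skipped and counted.
* One-error under ties at the top counts as an error only if no tied top label
  is true. Per-drug average precision uses stable descending order, ties
  broken by lower label index.
* Binarization threshold for Hamming loss and SEAD confusion metrics: 0.5,
  configurable.
* SEAD evaluation pools held-out positives against never-positive cells only;
  training positives are knowns, not predictions, and are excluded.

Fold assignment is balanced and a deterministic function of (seed, number of
units); SEND folds partition drugs, SEAD folds partition known-positive cells.

## Synthetic data

The generator plants exactly the structure the frame assumes: drugs in
`n_clusters` latent clusters; per view, a cluster prototype in `{0,1}^p` with
per-bit flip noise, and a per-drug informativeness mixture (a view at
informativeness γ draws a fraction γ of drugs from their prototype and the
rest from uniform noise, so γ=0 is a pure-noise view); associations are
Bernoulli draws at `association_rate_in_cluster` inside a cluster-owned block
of side-effect terms and `association_rate_background` outside. Defaults —
200 drugs, 50 terms, 5 clusters, two 100-descriptor views at informativeness
(0.9, 0.0), flip rate 0.05, rates (0.6, 0.02) — are sized so every
cross-validation experiment runs in seconds on one core. Sub-streams are
spawned per matrix from one seed, so adding a view never perturbs the
associations.

What passing on this data does and does not show: it demonstrates that the
pipeline recovers planted cluster structure well above a permuted-label null
and that the integration weights track view quality; it does not emulate the
marginal sparsity, term co-occurrence structure, or long-tailed side-effect
frequencies of real pharmacovigilance data, so absolute metric values here do
not forecast performance on curated datasets.

## Problem sizes used in checks

The acceptance script and test suite run: the 200-drug default bundle for
SEND 5-CV with a 20-permutation null; 20 independent 100-drug two-view
datasets for the weight-ordering experiment; the 200-drug association matrix
(seed 11) for SEAD 5-CV; 200 random 3-neighbor QPs against a 5151-point grid;
100 random cost vectors (K ≤ 10) against SLSQP; 50 random propagation
instances; and 30 random ≤8×6 metric instances against exhaustive
enumeration. These sizes were chosen as the smallest at which each property
is exercised with comfortable statistical margin.

## Known limitations

* Similarity construction is O(N·K³) via dense per-drug active-set solves;
  fine for N up to a few thousand, not tuned beyond that (exact kNN search is
  likewise dense).
* LN (λ=0) is supported but fragile by nature; on data with duplicated or
  low-rank neighborhoods it raises rather than returning an arbitrary vertex
  of the solution set.
* The directed graph is used as-is; no symmetrization option is exposed.
* `estimate_weights` fixes `Y = Y⁰` once; no alternating optimization over
  (Y, θ).
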