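# Methods

## Problem and model

Cell–cell communication analysis usually scores ligand–receptor (LR)
activity between whole cell types. That resolution is often too coarse:
within a sender type, only a subgroup of cells may express the relevant
ligands, and only a subgroup of the receiver type the matching receptors.
`cscpair` identifies **cell sub-crosstalk pairs (CSCPs)** — matched
sender/receiver cell subgroups with strong and mutually consistent
LR-mediated signaling — from two non-negative expression matrices and a
curated LR pair table.

### Definitional objective

Let `C_k^L`, `C_k^R` (k = 1..K) partition the sender and receiver cells.
Two scores define a good pairing:

* **Expression-difference score** (per subgroup, per side): the sum of
  squared deviations of member cells from the subgroup mean cell, plus
  squared deviations of the subgroup's genes from the mean gene, with cell
  vectors restricted to the side's LR gene rows and gene vectors restricted
  to member-cell columns. Low values = transcriptionally coherent subgroup.
* **Communication score** (per pair k): the bilinear form
  `sum_{gL,gR} w_{gL,k} a_{gL,gR} w_{gR,k}`, where `A = (a_{gL,gR})` is the
  binary ligand × receptor indicator and `w_{.,k}` are non-negative gene
  weights. High values = many active LR pairs between the two subgroups.

The target partition minimizes
`sum_k [ExprDiffer(C_k^L) + ExprDiffer(C_k^R) − Commun(C_k^L, C_k^R)]`.
This definitional objective is kept in the package (`cscpair.scores`) as a
partition-level diagnostic and as the brute-force oracle for small
instances; it is not the optimizer.

### Coupled NMF

Minimizing the definitional objective is equivalent (via the classical
correspondence between sum-of-squares clustering and non-negative matrix
factorization) to a coupled factorization of the ligand-gene × sender-cell
matrix `X^L` and receptor-gene × receiver-cell matrix `X^R`:

    min_{W,H ≥ 0}  ½‖X^L − W^L H^L‖²_F + (λ1/2)‖X^R − W^R H^R‖²_F
                   − λ2 tr((W^L)ᵀ A W^R) + μ(‖W^L‖²_F + ‖W^R‖²_F)

The k-th columns of the four factors jointly describe one CSCP candidate:
`W^L[:,k]` / `W^R[:,k]` weight its ligand / receptor genes, `H^L[k,:]` /
`H^R[k,:]` its sender / receiver cells. The trace term rewards loading
matched LR genes in the same component k, which is what couples the two
factorizations. A is oriented ligand-rows × receptor-columns throughout.

The solver (`cscpair.nmf.CoupledNMF`) uses multiplicative updates in the
fixed Gauss–Seidel order `W^L → W^R → H^L → H^R`:

    W^L ← W^L ⊙ (X^L(H^L)ᵀ + (λ2/2) A W^R) / (W^L H^L(H^L)ᵀ + 2μW^L)
    W^R ← W^R ⊙ (X^R(H^R)ᵀ + (λ2/2λ1) Aᵀ W^L) / (W^R H^R(H^R)ᵀ + 2μW^R)
    H^L ← H^L ⊙ ((W^L)ᵀX^L) / ((W^L)ᵀW^L H^L)
    H^R ← H^R ⊙ ((W^R)ᵀX^R) / ((W^R)ᵀW^R H^R)

with `eps = 1e-10` added to every denominator. Hard subgroup assignment is
`argmax_k H[k, j]` per cell (ties to the smallest k); gene membership is
`argmax_k W[g, k]` with `W[g, k] > 0`.

### Parameter selection

All four factors are initialized i.i.d. uniform on (0, 1]. After a
**warm-up** of 50 uncoupled rounds (λ2 = μ = 0), the weights are selected
from the warm residuals:

    λ1 = ‖X^L − W^L H^L‖² / ‖X^R − W^R H^R‖²
    λ2 = ‖X^L − W^L H^L‖² / (2 tr((W^L)ᵀ A W^R))
    μ  = ‖X^L − W^L H^L‖² / (2(‖W^L‖² + ‖W^R‖²))

each multiplied by a configurable multiplier, default **(1, 1000, 1)**. A
zero denominator sends that parameter to 0 with a logged warning. The
warm-up length is a design choice: the formulas need factors to evaluate,
and 50 uncoupled rounds give residuals that reflect the data rather than
the random initialization. Coupled updates then run until the relative
objective change stays below `tol = 1e-4` for 10 consecutive rounds, or 500
rounds. K defaults to 2; small K (2–3) is recommended when the subgroup
structure is unknown.

### Numerical choices in the solver

Three stabilizations are applied on top of the printed update rules; all
three are standard NMF practice and none changes the model:

1. **Scale gauge.** `W H` is invariant under `(W D⁻¹, D H)`. The raw
   objective is unbounded below once λ2 is large — scaling all factors by c
   scales both `−λ2·tr` and `μ‖W‖²` as c², and the selected λ2·trace
   exceeds μ·reg by the multiplier ratio (~1000×) — so unconstrained
   multiplicative updates overflow. After every round each W column is
   rescaled to unit L2 norm with the scale folded into H. Reconstruction is
   untouched; the coupling reward becomes bounded.
2. **Factor floor (1e-12).** Multiplicative updates cannot move an entry
   that reaches exactly 0. On cleanly separable data the warm-up can zero
   every cross-block entry, making the coupling trace exactly 0 and λ2
   degenerate. The floor keeps entries movable without affecting results at
   data scale.
3. **Column pairing.** The coupled objective ties sender subgroup k to
   receiver subgroup k, but when the selected λ2 is (near-)zero — e.g. the
   residual vanishes on noiseless data — the pairing is an unresolved
   gauge. After convergence the receiver columns are permuted to maximize
   `tr((W^L)ᵀ A W^R)` (exact linear assignment). With effective coupling
   the identity permutation is already optimal and nothing changes.

With λ2 = μ = 0 each sub-update is a classical Lee–Seung step, so the
objective is exactly non-increasing; with the selected coupled parameters
monotonicity is empirical (observed in ≥95% of rounds on structured data,
and the final objective never exceeded the initial one in our checks).

### Coupled consensus clustering

NMF results depend on initialization, so the factorization is run T times
(default 20; run t seeded `base_seed + t`). Each run's hard partition
becomes a binary **coupled connectivity matrix** over the joint cell index
(senders, then receivers): entry (i, j) is 1 iff cells i and j carry the
same subgroup index k — a sender in k co-clusters with a receiver in k.
The element-wise mean over runs is the **coupled consensus matrix**
(entries = co-clustering frequencies). Its rows are clustered with Ward
agglomerative clustering into K joint clusters; rows-as-features with
Euclidean distance is our documented choice (the alternative — treating
1 − consensus as a precomputed distance — is not exposed). We pass K
clusters rather than a fixed default of 2 so the procedure is coherent for
K > 2.

Joint clusters containing both sender and receiver cells are the reported
CSCPs; one-sided clusters are listed as *unpaired* (a CSCP requires both
sides by definition). The consensus has no factors of its own, so reported
gene sets and weights come from the run whose partition is closest (highest
adjusted Rand index, ARI) to the consensus partition, with run subgroups
matched to consensus clusters by maximum overlap (Hungarian assignment).

## Synthetic data

`cscpair.synthetic` generates the regime the method targets, so every
pipeline is testable without external downloads:

* **Planted CSCPs.** K subgroups per side, `cells_per_subgroup` cells each.
  Subgroup k expresses its own block of `genes_per_block` ligand (sender
  side) or receptor (receiver side) genes at negative-binomial count mean
  `signal` (variance m + m²/dispersion; Poisson at infinite dispersion);
  everything else sits at mean `baseline`. Counts are then per-cell scaled
  to 10,000 and log1p-transformed (the default normalization;
  raw matrices are also accepted). A `noiseless` flag substitutes the exact
  means — the zero-noise limit used by the exhaustive small-instance
  oracle. The generated LR table pairs ligand i with receptor i one-to-one;
  optional decoy genes never appear in A.
* **Spatial maps.** Each cell is placed at an isotropic Gaussian draw
  (std `spread`) around its CSCP's center, with both cell types mixed in
  each blob — the co-located-neighborhood structure that spatial data of
  communicating subgroups shows.
* **Masked samples.** With two labeled CSCPs, sample 1 keeps all CSCP-0
  cells plus floor(keep_fraction·n) (≥1) randomly kept CSCP-1 cells on both
  sides; sample 2 mirrors it (default keep_fraction 0.2).
* **Response cohort.** 9 responders / 20 non-responders (the class ratio of
  a typical checkpoint-blockade cohort), two CSCPs per patient. Responders
  carry elevated ligand/receptor means only within CSCP-0; a per-patient
  baseline shift (`patient_sd`) models inter-patient variability, which is
  what leaves the diluted cell-type-level signal only partially
  discriminative.

What the generators deliberately do **not** model: transcriptome-wide gene
correlation structure, batch effects, dropout beyond NB sparsity, doublets,
or realistic LR-table topology (real tables are many-to-many). Passing
tests on these fixtures show that the algorithms behave as designed in
their intended regime, not that any particular biological dataset contains
CSCPs.

### Fixture regimes (used by tests and the acceptance script)

| fixture | signal | baseline | dispersion | purpose |
|---|---|---|---|---|
| recovery | 8 | 2 | 5 | parameter recovery; consensus checks |
| noisy | 3 | 1 | 3 | L2-stability and LR-perturbation experiments |
| sparse | 5 | 0.02 | 10 | masked-sampling and spatial experiments |
| noiseless | 6 | 0 | — (exact means) | exhaustive small-instance oracle |

The noisy regime was chosen as the partial-recovery zone (single-run
ARI to truth ≈ 0.6): where recovery is perfect the coupling term is
redundant and stability/perturbation effects are invisible; where recovery
is zero nothing is measurable. The sparse regime makes the detection
fraction of a 20%-masked subgroup fall below the caller's 20% rule at
cell-type level, which is the mechanism that makes subgroup dilution hide
LR pairs.

## Evaluation procedures

* **Spatial co-location.** For each simulated field of view, the mean
  Euclidean sender–receiver distance within each CSCP is compared with the
  whole-map cross-type mean; a Wilcoxon signed-rank test is taken over
  FOVs. Distances are means over all cross pairs.
* **Masked-sampling reproducibility.** CSCPs are re-identified in each
  masked sample; a permutation LR caller is run at cell-type level (all
  kept cells) and per CSCP (calls tagged by pair index, sample-2 indices
  aligned to sample 1 through shared-cell overlap). Reported: the Jaccard
  similarity of the two samples' call sets at each level. The caller scores
  a pair as the mean of (mean ligand expression in senders, mean receptor
  expression in receivers), builds the null by permuting the
  sender/receiver split of the pooled cells, uses the positively biased
  estimator p = (#null ≥ observed + 1)/(n_perm + 1) so p is never 0, and
  additionally requires detection (> 0) of the ligand in > 20% of senders
  and the receptor in > 20% of receivers. Both genes must be measured in
  both populations (the pooled null needs them); other pairs are skipped
  and logged.
* **Response prediction.** Per-patient features are the mean receptor
  expression over receiver cells (optionally averaged with mean ligand
  expression over sender cells), at cell-type level (one value), per CSCP
  (concatenated), or per receiver subtype (receptor-only — a two-gene
  variant is undefined there because no sender/receiver subtype matching
  exists). A linear maximum-margin classifier (SVC) is trained on repeated
  stratified 4/5–1/5 splits (default 100 repeats; the 9/20 imbalance is
  kept, not rebalanced) and mean held-out ROC AUC reported; separately,
  features are projected to 1-D along the two-class Fisher discriminant
  (within-class scatter ridged by 1e-6 if singular), z-scored across
  patients, and the two-sample pooled t statistic between classes computed.

Statistics: the Wilcoxon signed-rank wrapper drops zero differences, uses
the exact null for n ≤ 25 and the normal approximation above, and returns
the signed statistic W⁺ − W⁻; the pooled-variance t test returns (0, 1)
for zero variance with equal means and a capped statistic (±1e9, logged)
for zero variance with unequal means. Jaccard of two empty sets is defined
as 1 (logged).

## Problem sizes and determinism

Default experiment sizes (tests and `scripts/acceptance.py`) are 2 CSCPs ×
30–50 cells per subgroup × 6–10 genes per block, T = 3–5 consensus runs,
200–1000 caller permutations, 8–16 replicates per perturbation point —
sizes at which every distributional claim stabilizes while the full
acceptance run completes in seconds. All randomness flows from explicit
integer seeds (`numpy.random.default_rng`); identical seeds give
byte-identical outputs, and the CLI writes a manifest (resolved config,
seeds, input hashes) next to every result.

## Known limitations

* Exactly two cell types per analysis; many-to-many (≥3 type) CSCPs are out
  of scope.
* Hard, non-overlapping membership; a cell belongs to exactly one CSCP.
* K must be supplied; beyond preferring small K there is no automatic
  selection.
* The λ2 multiplier 1000 is the published default; nothing guarantees it
  generalizes to arbitrary data, so it is exposed as configuration.
* The coupled phase is a heuristic: objective monotonicity under the
  selected parameters is an empirical observation, not a theorem.
* Gene symbols are matched case-sensitively after whitespace trimming; no
  homolog/species conversion is performed.
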