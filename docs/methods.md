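# Methods

## Model

Log-expression of gene g on array a (array a sorted from cell population
p(a)) is modelled as

    y[g,a] = μ + β[p(a)] + S[a] + G[g] + GC[g,p(a)] + ε[g,a],

with mutually independent normal random effects: S (array, variance σ_S²),
G (gene, σ_G²), GC (gene-by-population, σ_G.CP²) and residual ε (σ_ε²).
The cell-population means β are fixed effects; because arrays are
normalized upstream, no population-level shift is expected and the fixed
effect mainly serves as a guard. The analysis has two stages: REML
estimation of the variance components with BLUP extraction of GC, then an
empirical-Bayes classification of the GC estimates per population under a
two-component zero-mean normal scale mixture.

Stage two treats each population's GC column as draws from
(1 − π₁)N(0, σ₀²) + π₁N(0, σ₁²) with σ₁ > σ₀. The posterior probability of
the wide component given an effect x is the DE probability; genes with
posterior > 0.8 are called DE (equivalently |x| > c, where the cutoff c
solves posterior(c) = 0.8 and is reported). The model-based FDR of a call
set is mean(1 − posterior) over called genes — bounded above by
1 − threshold = 0.2 by construction — and the overall FDR is the
DE-count-weighted mean across populations.

## REML on the collapsed representation

The fixed effects are array-level and every gene is observed on every
array. Rotating the gene dimension onto the gene-mean direction and its
orthogonal complement block-diagonalizes the marginal covariance into

  * G − 1 identical contrast blocks C = σ_G² J_A + σ_G.CP² B + σ_ε² I_A,
  * one gene-mean block M = C + G σ_S² I_A,

where A is the number of arrays, J the all-ones matrix and B the
same-population indicator. The restricted likelihood, its score and the
average-information (AI) matrix therefore depend on the data only through
the A-vector of per-array gene means and the A×A within-gene cross-product
matrix; every iteration costs O(A³) regardless of the gene count and no
dense covariance is ever formed. BLUPs follow in closed form from the same
quantities and have been verified to machine precision against a dense
solve of Henderson's mixed-model equations (see the test suite), and the
whole fit against lme4's REML on the same data.

Optimization runs 10 EM-REML iterations first (each EM update is the
scaled gradient step σ_i² ← σ_i² + (2σ_i⁴/q_i)·score_i, monotone in the
restricted likelihood), then switches to AI updates with step-halving back
toward the current point whenever a proposal would decrease the
likelihood, falling back to the EM step if halving fails. Convergence is
declared when the relative change in restricted log-likelihood is below
1e-8 and the maximum relative parameter change below 1e-6, with an
iteration cap of 200. Variance proposals are floored at 1e-10; a component
held at the floor for three consecutive iterations is treated as zero:
reported as exactly 0, given zero BLUPs, and removed from the AI system
(its SE is reported as 0). Standard errors come from the inverse AI matrix
over the free components.

The cell-population test is a Wald F on the GLS estimates with denominator
df = arrays − populations (the array stratum). This is a deliberate
simplification: when the gene-level variance components dominate the
contrast variance they are estimated from thousands of genes, the
denominator behaves as if its df were much larger, and the test becomes
conservative (simulated null rejection ≈ 0.01 at nominal 0.05 under the
reference conditions). It never becomes liberal, which is the acceptable
direction for a guard test.

## Mixture EM

With both component means fixed at zero the M-step is closed form: π₁ is
the mean responsibility of the wide component and each σ² a
responsibility-weighted mean square. The likelihood has degenerate spikes
as either SD → 0 at data points near zero; the fitter floors the SDs at
1e-6·SD(x) and runs five starts — the default initialization
(π₁ = 0.25, σ₀ = 0.5·SD(x), σ₁ = 2·SD(x)) plus four jittered variants from
a fixed sub-seeded RNG — keeping the best-likelihood *converged* chain, or
the best unconverged chain flagged as such (downstream classification
refuses a flagged fit). Components are always reported with σ₀ ≤ σ₁.

Convergence is an absolute log-likelihood change below 1e-9. The iteration
cap is 20,000: EM converges linearly, and with weakly separated components
(σ₁/σ₀ around 1.5, which BLUP shrinkage routinely produces) several
thousand iterations are needed to meet that tolerance; a cap of a few
thousand would flag such fits spuriously. Iterations are O(n), so the cap
is immaterial to runtime at these sample sizes.

Two behaviours at the identifiability boundary are worth knowing. If the
data are a single Gaussian, π₁ is unidentified and the fit collapses to
σ₀ ≈ σ₁ with a log-likelihood essentially equal to the single-Gaussian
fit; any π₁ is then admissible and calls should not be interpreted. If the
two true components are barely separated, the EM can prefer a solution in
which the wide component absorbs nearly all mass and almost every gene
exceeds the posterior threshold; the FDR bound still holds, but a call set
comprising most of the genome signals this mode and should be treated as a
failed separation, not as biology.

## Synthetic-data generator

The generator draws every term of the model exactly as written:
S ~ N(0, σ_S²) per array, G ~ N(0, σ_G²) per gene, residuals i.i.d., and
GC either gaussian (variance σ_G.CP²) or, per population, from the
two-component mixture with the wide-component indicator retained as the
ground-truth DE label. Each term uses its own child stream of one seed
sequence, so enlarging the gene set leaves array effects untouched, and
identical configurations are bitwise-reproducible.

The reference configuration mirrors the four-population bovine mammary
design: populations with 3/2/3/3 replicate arrays, σ_S² = 0.036,
σ_G² = 5.44, σ_G.CP² = 0.672 (gaussian mode) or the per-population fitted
mixtures (mixture mode), grand mean 7 on the log₂-RPKM scale and zero
population fixed effects. The residual variance was never reported by the
source analysis; 0.25 is used — small against σ_G², and with replicate
arrays in every population it does not confound the interaction component.
The gene count (2,000) is likewise a package choice: large enough to pin
the gene-level components, small enough that a full REML fit takes
milliseconds. Because the real arrays measured many more genes, published
absolute DE counts (n_DE per population) are not reproducible from
simulation and are not targets; parameter recovery is.

What the generator does not emulate: count-level noise and library-size
effects (it works directly on the log scale the model is written in),
correlated genes (pathway structure), population-specific residual
variances, and array batch effects beyond the exchangeable array term.
Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to their
violation on real data.

## Clustering and enrichment

DE-gene profiles (the four BLUP interaction values) are standardized per
gene to zero mean and unit SD, clustered by Ward-linkage agglomeration on
Euclidean distance, and the dendrogram cut to exactly 2^levels clusters
(default 3 levels → 8 clusters, the third binary splitting level).
Distance, linkage and the agglomerative direction are package choices —
the displayed heatmap structure this reproduces does not pin them down —
and are validated against a naive O(n³) agglomeration oracle. Genes are
processed in lexicographic id order so merge ties break deterministically;
a constant profile (SD 0) is kept unstandardized and logged. Cutting at
successive levels yields nested partitions.

Enrichment is one-sided hypergeometric over-representation: for a gene set
of size n in a universe of size N, a term with K members and overlap k has
p = P(X ≥ k), BH-adjusted across terms and flagged at FDR < 0.05. The
universe defaults to all genes in the fitted dataset (not the annotation's
union), which is the correct conditioning for sets derived from that
dataset; it is overridable. GO DAG structure and ortholog mapping are out
of scope — the map is a user-supplied TSV or GMT.

## Numerical and design notes

  * BLUP interaction estimates cannot recover a gene's average interaction
    level: with four populations the per-gene mean of GC (variance
    σ_G.CP²/4) is absorbed almost entirely by the gene effect, whose
    variance is an order of magnitude larger. The attainable correlation
    with simulation truth is ≈ 0.83 raw and > 0.93 after per-gene
    centering; recovery tests assert both at their attainable levels.
  * Classification at a zero effect estimate with posterior above the
    threshold (a measure-zero event) is assigned to neither sign and
    skipped, with the gene excluded from the call set.
  * An empty call set reports FDR as undefined (None), never 0; the overall
    FDR over all-empty call sets raises rather than fabricating a number.
  * Missing expression cells are rejected on construction; the design
    requires ≥ 2 genes, ≥ 2 populations and replicate arrays in at least
    one population, otherwise the confounded terms are named in the error.
  * All pipeline artifacts are TSV/JSON with sorted keys and no
    timestamps; a rerun with the same configuration and seed is
    byte-identical.

## Problem sizes

Default verification runs use 2,000-gene cohorts (11 arrays) for
mixed-model recovery — 20 replicates for the averaged variance-component
checks — and 20,000-draw samples (10 replicates) for mixture recovery,
sizes at which the Monte-Carlo standard errors are small enough to make
3-SE recovery checks meaningful while the full suite stays fast.
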