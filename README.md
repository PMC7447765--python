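# demix

Two-stage differential-expression (DE) analysis for expression profiles of
sorted cell subpopulations, as used to compare four bovine mammary
epithelial fractions sorted by CD49f and P-Cadherin surface expression
(3/2/3/3 replicate arrays; deposited data: GEO series GSE148447). The
package implements both stages as a reusable, fully tested pipeline and
ships a synthetic-data generator with the same statistical structure, so
every stage runs and is verified without any download.

## The model

**Stage one** fits a crossed random-effects linear mixed model to all
log-expression values jointly, by REML:

    logExpr[g,a] = μ + CellPop[p(a)] + Sample[a] + Gene[g]
                   + Gene.CellPop[g,p(a)] + ε[g,a]

where `Sample ~ N(0, σ_S²)` is the array effect, `Gene ~ N(0, σ_G²)` the
gene effect, `Gene.CellPop ~ N(0, σ_G.CP²)` the gene-by-population
interaction — the quantity of scientific interest — and `ε ~ N(0, σ_ε²)`
the residual. Variance components get standard errors from the inverse
average-information matrix; the interaction effects are extracted as BLUPs
from the mixed-model equations; the cell-population fixed effect is tested
with a Wald F-test.

**Stage two** models each population's interaction estimates as a
two-component zero-mean normal scale mixture,

    f(x) = (1 − π₁) N(x; 0, σ₀²) + π₁ N(x; 0, σ₁²),   σ₁ > σ₀,

fitted by EM: the narrow component is non-DE noise, the wide component DE
signal, and π₁ the DE fraction. A gene is called DE when its posterior
probability of the wide component exceeds 0.8, signed up/down by the
effect's sign. The model-based FDR of a call set is the mean of
(1 − posterior) over called genes, and the overall FDR the DE-count-weighted
mean across populations. Downstream utilities compute exclusive
per-population up/down sets, cut a Ward dendrogram of standardized DE
profiles into 2³ = 8 pattern clusters, and test gene sets for annotation
over-representation (hypergeometric upper tail, Benjamini–Hochberg FDR at
0.05).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort generated at the reference conditions (2,000 genes, four populations
with 3/2/3/3 arrays, interaction effects drawn from each population's
fitted mixture):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_fit_mixed_model.py
python analysis/03_call_de_genes.py
python analysis/04_exclusive_sets.py
python analysis/05_cluster_profiles.py
python analysis/06_enrichment.py
```

Step 02 prints the REML fit of the cohort:

```
REML converged in 13 iterations
  array (sample) variance:     0.0632 +/- 0.0338
  gene variance:               5.176 +/- 0.168
  gene x population variance:  0.3880 +/- 0.0088
  residual variance:           0.2478 +/- 0.0030
cell-population effect: F(3,7) = 0.27, P = 0.85
```

The gene variance recovers its generating value (5.44) within sampling
error; the gene-by-population value 0.388 is the marginal variance of the
mixture the effects were drawn from, i.e. the average of
(1 − π₁)σ₀² + π₁σ₁² over the four populations. The null population effect
is correctly non-significant. Step 03 then fits the mixtures and calls DE
genes:

```
CD49f_high/P-cad_neg: pi1=0.376 sigma0=0.335 sigma1=0.759 n_de=198 fdr=0.056 precision=0.939
overall FDR (DE-count-weighted): 0.061
```

`precision` compares the calls against the simulation's ground-truth DE
labels: ~94% of the genes called DE in the stem-cell-enriched population
really were drawn from the wide component. Steps 04–06 print the exclusive
up/down set sizes, the 8 cluster sizes, and which (synthetic) annotation
terms each cluster is enriched for.

The same pipeline runs from a shell on real data:

```sh
demix run-all --expression expr.tsv --metadata meta.tsv \
      --log-transform log2_offset --out results/run --seed 1
```

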