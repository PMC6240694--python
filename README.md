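# coexnet

Weighted gene co-expression network analysis (WGCNA) for **dose-response
transcriptomes** — the setting of estrogenicity screens where cells are
profiled across exposure concentrations spanning picomolar to micromolar
(e.g. estradiol vs. the xenoestrogen bisphenol A in MCF-7 cells), and the
question is which *groups* of co-regulated genes track dose, whether that
structure is conserved across exposures, and which regulators and hub genes
sit behind it.

## What it computes

For an expression matrix $X$ (genes × samples) of one condition:

1. **Signed weighted network.** Pairwise Spearman correlation $r_{ij}$,
   soft-thresholded into a signed adjacency
   $a_{ij} = \left(\tfrac{1 + r_{ij}}{2}\right)^{\beta}$ with $\beta = 10$,
   so anti-correlated genes get near-zero weight instead of high weight.
2. **Topological overlap.** With connectivity $k_i = \sum_{u \ne i} a_{iu}$,

   $$\mathrm{TOM}_{ij} = \frac{\sum_{u \ne i,j} a_{iu}a_{uj} + a_{ij}}
                              {\min(k_i, k_j) + 1 - a_{ij}},$$

   and $1 - \mathrm{TOM}$ is the clustering dissimilarity.
3. **Modules.** Average-linkage clustering plus an adaptive (dynamic) tree
   cut — deep-split level 2, minimum module size 30 — followed by kME-based
   cleanup, merging of modules whose eigengenes are closer than 0.25 in
   $1 - \mathrm{cor}$, and significance-based gene reassignment
   (threshold 0.2). Unassigned genes are grey.
4. **Dose statistics.** Each module's eigengene (first principal component
   of the standardized member expression) is correlated with the ordinal
   dose level; $p = 2\,P\!\left(T_{n-2} \ge |r|\sqrt{\tfrac{n-2}{1-r^2}}\right)$,
   and modules with $p < 0.01$ are dose-responsive.
5. **Consensus across conditions.** Per-condition TOMs on the shared
   top-N gene universe are calibrated (95th-percentile scaling) and combined
   by entrywise minimum; consensus modules (minimum size 100) get a
   per-module consensus correlation: the weakest per-condition $r$ when all
   conditions agree in sign (largest $p$), NA otherwise, selected at
   $p < 0.05$.
6. **Regulators and hubs.** One-sided Fisher exact (hypergeometric tail)
   enrichment of user-supplied gene sets (GMT; e.g. TF-target libraries) in
   each significant module with Benjamini–Hochberg adjustment, and hub genes
   as the intersection of the top 10% by kME and by degree in a user-supplied
   interaction network. Condition-unique gene lists (module genes of one
   network absent from another's universe) support cross-exposure contrasts.

Inputs are plain files: expression TSV (genes in rows), metadata TSV
(sample_id, condition, dose_molar, replicate), GMT gene sets, edge-list TSV.
A seeded synthetic-data generator plants modules with known dose effects,
TF target sets and interaction edges, and ships the ground truth for scoring
recovery — it is the package's benchmark and test bed.

## Worked example

```python
from coexnet import (PipelineConfig, SyntheticConfig, generate,
                     run_condition, score_recovery)

data = generate(SyntheticConfig(seed=0))   # 5 planted modules, 1500 background
result = run_condition(data.expression, data.metadata,
                       PipelineConfig(condition="estrogen"))
print(result.significant[["module", "r", "p"]])
```

prints

```
module      r        p
yellow  0.808 2.53e-09
 green  0.766 5.05e-08
  blue -0.722 6.69e-07
```

— the three planted dose-responsive modules (latent dose correlations
+0.7, +0.7, −0.7), recovered with `score_recovery(...).ari == 1.0` against
the planted partition; the null and low-dose-peak modules are found as
co-expression modules but fail the monotonic dose test. The
`examples/` directory has one short script per capability (single network,
dose statistics, consensus, enrichment, hubs, and the `coexnet` CLI
workflow from the shell).

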