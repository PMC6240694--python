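# Methods

This note records the models, parameter choices and numerical decisions
behind `coexnet`, and what the synthetic benchmark does and does not show.

## Network model

Co-expression is measured by Spearman correlation (Pearson on per-gene
midranks), which is invariant to monotone normalization differences and
robust to the heavy tails of intensity data. A gene with zero rank variance
carries no ordering information; its correlations are defined as 0 and the
event is logged.

The signed adjacency $a_{ij} = ((1+r_{ij})/2)^\beta$ maps $r = -1, 0, 1$ to
$0, 2^{-\beta}, 1$: anti-correlated genes are separated rather than grouped,
and soft thresholding with $\beta = 10$ (the package default, standard for
signed networks) suppresses weak correlations continuously instead of via a
hard cutoff. No automatic $\beta$ sweep is provided — the exponent is part
of the declared analysis, recorded in the run report.

The topological overlap matrix uses the classical (unsigned-formula) TOM
applied to the signed adjacency. The shared-neighbor term is one matrix
product, so a 10,000-gene network is a single dense block; larger inputs
are an error suggesting a stronger expression filter rather than a silent
block decomposition (`max_block_size`, default 10,000). A triple-loop
evaluation of the formula is kept in the test-suite as the oracle.

## Gene filtering

Each network is built from the top-N genes (default 10,000) of its sample
subset by *rank-mean expression*: genes are ranked within each sample
(midranks for ties) and ordered by the mean rank across samples. This is
scale-free per sample; ties in the final ordering break lexicographically
by gene id so the selection is deterministic. Sample subsets are defined by
condition and an optional strict dose ceiling (e.g. "below 12.5 µM" for a
low-dose re-analysis); doses are stored in molar units so such thresholds
compare without unit guessing.

## Module detection

Average linkage (UPGMA, via scipy) clusters the TOM dissimilarity. The
dendrogram is cut adaptively:

* A static cut at 0.99 × the maximum merge height defines candidate
  branches.
* Heights are referenced to $h_{\mathrm{ref}}$, the 5th-percentile merge
  height: with soft thresholding even within-module dissimilarities sit
  high in [0, 1], so tightness must be judged relative to the tightest
  merges the tree actually contains. The deep-split level maps to
  (max core scatter, min gap) = {0: (0.64, 0.27), 1: (0.73, 0.2025),
  2: (0.82, 0.135), 3: (0.91, 0.0675), 4: (0.95, 0.0375)}, applied as
  scatter ≤ $h_{\mathrm{ref}} + s\,(h_{\mathrm{cut}} - h_{\mathrm{ref}})$
  and gap ≥ $g\,(h_{\mathrm{cut}} - h_{\mathrm{ref}})$. Default deep split: 2.
* A subtree's *core scatter* is its mean internal merge height; its *gap*
  is measured from its attach height down to that typical internal height,
  so stray leaves chaining onto a branch cannot erase its separation.
* A branch whose two children both qualify (size ≥ minimum, scatter and
  gap within bounds) is split; a branch with a qualifying split anywhere
  below it is descended (chained stragglers go grey, to be rescued later);
  otherwise a branch whose own scatter qualifies is accepted whole. Genes
  in no accepted branch are grey.

This is a deliberate, faithful variant of the published adaptive tree-cut:
bit-compatibility with the R reference implementation (with its PAM stage
and trimming micro-heuristics) is not a goal; recovering planted structure
is the contract the tests enforce. Minimum module size is 30 (100 for
consensus networks).

After the cut: (1) genes whose own-module kME falls below 0.3 are sent to
grey and modules dropping under the size floor disband (the standard
post-cut cleanup; a loose branch of mutually unrelated genes dissolves
here); (2) modules whose eigengenes are closer than the merge cut height
0.25 in $1-\mathrm{cor}$ are unioned, iterating to a fixed point so merging
is idempotent; (3) a single reassignment pass moves a gene to another
module when its correlation p-value there is below 0.2 × the p-value
against its own eigengene *and* its kME improves — one pass, evaluated
against fixed eigengenes, so termination is trivial. Final labels are the
conventional color sequence by decreasing size, with ties broken by the
lexicographically smallest member so labelling is permutation-equivariant.

Eigengenes are computed by SVD of the z-scored member×sample matrix (no
centering across genes); the profile is unit-norm with sign chosen so the
mean member correlation is non-negative; variance explained is
$s_1^2/\sum s_k^2$. A single-gene module's eigengene is its normalized
z-profile.

## Dose-trait statistics

Dose spans eight decades, so the default trait encoding is the *ordinal
dose level* (sorted unique doses → 1..L), which no single decade can
dominate; log10 (zero doses mapped one decade below the smallest positive
dose) and linear encodings are options. Eigengene–trait association uses
Pearson correlation with the Student-t test
$t = r\sqrt{(n-2)/(1-r^2)}$, two-sided; $|r|=1$ gives p = 0 exactly.
Selection is strict ($p < \alpha$, default 0.01), rows sorted by
descending correlation. No multiple-testing correction is applied across
modules at this step, matching standard practice for module–trait tables.

## Consensus networks

The consensus universe is the intersection of the per-condition top-N
lists (logged). Per-condition TOMs are calibrated by single-quantile
scaling: each matrix is multiplied by $Q_{\mathrm{ref}}/Q_k$ where $Q_k$
is its off-diagonal 95th percentile and $Q_{\mathrm{ref}}$ the median of
those — full quantile normalization is deliberately avoided as harder to
reason about; the scale factors are recorded in the run report, and
calibration can be switched off. The consensus TOM is the entrywise
minimum. Module detection then runs with minimum size 100; eigengene-based
cleanup, merging and reassignment use the first condition's expression as
the reference (a recorded design choice — the alternative, per-condition
votes, adds complexity without changing what the tests measure). Trait
tables are computed per condition; the consensus row for a module is the
smallest-magnitude correlation with the largest p-value when all
conditions agree in sign, NA otherwise, selected at p < 0.05.

## Enrichment, unique genes, hubs

Gene-set enrichment is the one-sided Fisher exact test — the
hypergeometric upper tail $P(X \ge \mathrm{overlap})$ — with the universe
defined as the network's analyzed genes intersected with the library's
gene space (a defensible, explicit background; logged). BH adjustment is
applied within each module × library family. Sets with no universe overlap
are skipped and logged. Condition-unique genes are the union of one
network's significant-module genes minus the other network's analyzed
universe.

Hubs are "high kME and high degree" made explicit: the top fraction
(default 0.1, ceil, ties broken by gene id so shrinking the fraction
shrinks the list) of a module by own-module kME, intersected with the top
fraction by degree in the module-induced subgraph of the supplied edge
list, ranked by kME.

## Synthetic benchmark

The generator emulates a multi-condition dose-response microarray design:
per condition, 18 dose levels (vehicle 0 plus half-log steps from 1 pM to
100 µM) × 2 replicates = 36 samples. Each planted module has a latent
factor per condition, $m(s) = \alpha f(\mathrm{dose}_s) +
\sqrt{1-\alpha^2}\,\eta_s$, with $f$ a standardized response shape
(monotonic in ordinal dose; a unimodal low-dose bump emulating weak
activation at low concentrations; or null) — so $\alpha$ is the factor's
dose correlation. Members load as $x_{gs} = \lambda m(s) +
\sqrt{1-\lambda^2}\,\varepsilon_{gs} + \mathrm{offset}_g$, making
$\lambda$ the expected gene–factor correlation. The first member is a
designated hub with loading midway between $\lambda$ and 1 and a dense
edge neighborhood. Defaults: 5 modules × 100 genes at $\lambda = 0.8$
(dose effects +0.7, −0.7, +0.7 monotonic, 0.5 low-dose peak, null), 1,500
background noise genes, unit noise SD. TF target sets cover half of their
target module plus random decoys; edges are within-module Erdős–Rényi
(p = 0.15) over a sparse background (p = 0.002). An optional
`active_offset` shifts member expression in conditions where a module is
active, emulating condition-specific induction (off by default).

What this does *not* model: probe-level microarray noise, normalization
artifacts, batch effects, correlated background structure, or any real
regulatory biology. Passing the recovery benchmarks therefore shows the
pipeline's machinery is correct and well-calibrated for block-structured
latent-factor data at realistic sample sizes — not that any particular
biological claim holds on real arrays.

Recovery is scored by adjusted Rand index over the genes truly in modules
(background handling does not mask partition errors), best-match Jaccard
per planted module, and sign agreement between detected module–dose
correlations and planted $\alpha$.

## Determinism, degenerate inputs, problem sizes

Every stage is deterministic: identical inputs and configuration give
byte-identical tables, and permuting gene order permutes the results
(labels included, thanks to the tie-break rules). The run report isolates
stage timings in a single `timings` key so reports are otherwise
comparable across reruns. Degenerate cases have defined behavior:
constant genes (correlation/kME 0, logged), single-gene modules,
minimum module size exceeding the gene count (all grey, warning),
all-zero doses under log10 (error), empty enrichment universe (error),
duplicate gene rows at load (highest-mean row kept, logged).

The test-suite and the acceptance script run the benchmark at its stated
size (2,000–2,100 genes, 36–72 samples), which the package's own choice of
single-block dense linear algebra completes in seconds per network; the
same code path scales to the 10,000-gene single-block ceiling.
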