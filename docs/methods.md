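# Methods

This note documents the models and procedures implemented in `modulenet`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter.

## Co-expression network and modules

Gene–gene similarity is the Pearson correlation `C` across samples
(constant genes are a hard error — their correlation is undefined). The
adjacency is the unsigned power transform `A = |C|^β` with a zeroed
diagonal; the soft threshold β is scanned (default grid 1–12) and chosen as
the smallest power whose *signed scale-free fit* reaches R² ≥ 0.85: the
whole-network connectivity `k_i = Σ_j A_ij` is binned into 10 equal-width
intervals and `log10(frequency)` regressed on `log10(mean k)`, with R²
signed by `−slope` so only decreasing degree distributions qualify. If no
power qualifies, the argmax is used and flagged. Equal-width binning is
the convention of the scale-free fit index used with weighted
co-expression networks; equal-count binning would make the regressand
constant by construction.

The unsigned topological overlap is

    TOM_ij = (Σ_{u≠i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij),
    TOM_ii = 1,

and `1 − TOM` is the clustering dissimilarity. The implementation is
matrix-form (`A @ A` with zeroed diagonal) and is checked entry-wise
against a double-loop reference to 1e-12 in the tests.

**Module detection.** Average-linkage hierarchical clustering of `1 − TOM`,
cut with an adaptive static rule: among the dendrogram's own merge heights
up to `cut_height_fraction` (default 0.99) of the root height, the lowest
height that maximises the number of clusters of size ≥ `min_module_size`
(default 30) is used. A single fixed fraction of the root height proved
brittle here: with `1 − TOM` all merges concentrate just below 1, the
heights at which distinct module branches complete are data-dependent, and
a cut near the root fuses modules with background. The adaptive rule is a
deterministic stand-in for dynamic tree cut. Clusters below the minimum
size become `unassigned`.

Each module is summarised by its **eigengene**: the first right-singular
vector (sample scores, unit norm) of the row-standardised module
submatrix, sign-fixed so its correlation with the module's mean profile is
non-negative — making every downstream statistic invariant to the SVD's
sign convention. Detected modules are then *cleaned by module membership*:
genes whose |kME| (correlation with their own module eigengene) falls
below `kme_clean` (default 0.7, the same membership threshold the
core-gene filter uses; 0 disables) are unassigned, and the size filter is
re-applied. Finally, module pairs whose eigengene dissimilarity
`1 − cor(ME_i, ME_j)` is below `merge_cut` (default 0.25, common practice)
are merged iteratively, closest pair first, recomputing eigengenes after
every merge. Labels are canonical (`M1`, `M2`, … by decreasing size, ties
by first gene id), so results are invariant to gene input order.

**Disease modules.** A module qualifies when (i) the Pearson correlation
of its eigengene with the 0/1 case indicator is significant (two-sided t
transform, `alpha` 0.05), (ii) the case/control shift of the eigengene is
significant by two-sided Wilcoxon rank-sum after BH correction across
modules (FDR 0.05) — the rank-sum test was chosen as a distribution-free
default for a group-difference test that was otherwise unspecified — and
(iii) the module is enriched for the disease-gene catalogue by the
upper-tail hypergeometric test (`alpha` 0.05) against the expression
universe.

## Core genes and over-representation

Within disease modules, a gene is *core* when |kME| > 0.7 **and** its
individual two-class ranking AUC > 0.8. The AUC is the Mann–Whitney
probability with ties counted ½, oriented as `max(a, 1 − a)` so that
under-expressed markers qualify symmetrically (the orientation was left
open by the thresholds' source; the symmetric choice is the inclusive
one). Over-representation of arbitrary GMT collections uses the same
upper-tail hypergeometric with BH FDR across the collection; query members
outside the universe are dropped and counted.

## Disease-network statistics

Node classes are `disease` (catalogued), `candidate` (core genes), and
`other`. For a candidate with degree `d` and `c` disease neighbours:

* `interaction_ratio = c / d` (so `ratio × degree = count` exactly);
* `p_count_hyper`: upper-tail hypergeometric of `c` when drawing `d`
  neighbours from the other `N − 1` nodes containing `K` disease nodes;
* `mean_sp_disease`, `mean_sp_candidate`: mean unweighted shortest-path
  lengths to reachable members of each class (self and unreachable nodes
  excluded, the latter counted — imputing infinities would dominate the
  means on fragmented graphs);
* `shortest_ratio = mean_sp_disease / mean_sp_candidate` (< 1 means
  disease-proximal);
* `degree_percentile`: fraction of all network nodes with degree ≤ the
  candidate's.

The permutation null shuffles node-class labels with class counts fixed,
which preserves every degree and isolates the class signal; the focal
node is excluded from the permuted class sets. Per candidate,
`p_ratio_perm` is upper-tail on the interaction ratio and
`p_shortest_perm` lower-tail on the shortest-path ratio, both with the
plus-one rule (`p ≥ 1/(n_perm+1)`, never 0); default 1000 permutations.
Degree-preserving edge rewiring (double edge swaps with classes fixed) is
available via `null_model="rewire"` but label shuffling is the default — it
is cheaper and matches a "random perturbation" background. Key genes are
candidates with all of `p_ratio_perm ≤ α`, `p_shortest_perm ≤ α`,
`p_count_hyper ≤ α`, and `degree_percentile ≥ 1 − α` (α default 0.05).

Pre-ranked GSEA on any node score (here, network degree) uses the
weighted running sum (hits add `|score|^w / Σ_hits |score|^w`, misses
subtract `1/(N − n_hits)`; default weight 1), a gene-label permutation
null (default 1000), one-tailed p among same-sign null scores with the
plus-one rule, NES = ES / mean |same-sign null ES|, and BH FDR across sets.

## Drug–target proximity

For disease set *S* and drug targets *T* on the interactome,

    d(S, T) = (1/|T|) Σ_{t∈T} [ min_{s∈S} dist(s, t) + ω_t ],
    ω_t = −ln(deg(t) + 1)  if t ∈ S,  else 0,

computed from a single multi-source BFS from *S*. Targets absent from the
network or unreachable from *S* are dropped and counted; a drug with no
usable target is reported with a note rather than failing the screen. The
null draws `n_perm` (default 1000) uniform node sets of the same size
without replacement; `z = (d_obs − μ_null)/σ_null` and
`p_emp = (1 + #{d_null ≤ d_obs})/(1 + n_perm)` — *smaller* distance means
proximal, so selection is in the negative-z/low-p direction, the
convention of the network-proximity literature. A degree-binned null
(each null target drawn from the degree quantile bin of the corresponding
observed target) is available behind `degree_matched=True` but off by
default, matching the plain uniform description of the reference
distribution. "Global FDR" is BH across all screened drugs (cutoff 0.05).
Per-drug child seeds are derived from the screen seed keyed by a CRC of
the drug id, so results are independent of input order.

## Diagnostic panel

Features (panel-gene rows, samples × genes) are standardised with
training-set mean/sd stored in the model; the classifier is a linear SVM
with C = 1 (both exposed in config — the original setting named only
"SVM", and the linear kernel with unit cost is the minimal choice for a
3-feature panel). Cross-validation is stratified k-fold (default 10,
degrading to the smallest class size with a warning); out-of-fold
predictions are pooled into a single confusion matrix and a single ROC
built from decision-function scores, because whole-cohort counts are the
natural report for cohorts of 10–34 samples. AUC is the trapezoidal area
and equals the Mann–Whitney statistic of the scores (cross-checked in the
tests).

## Synthetic generator

`simulate_expression` draws, per planted module, a per-sample latent
factor `f ~ N(0,1)`; disease modules add `effect` to the case-sample
factor mean; member genes are `loading·f + N(0, noise_sd²)` and background
genes pure `N(0,1)`. The expected within-module correlation is
`loading²·var(f) / (loading²·var(f) + noise_sd²)`. Defaults — 400 genes, 4
modules of 50, 2 disease modules, 8+8 samples, effect 2, loading 0.8,
noise 0.6 — give within-module correlations around 0.6–0.8 at cohort sizes
typical of the small case/control microarray studies this pipeline
addresses. The latent-factor model was chosen over sampling explicit
correlation matrices: it is cheap and gives analytic control of the
within-module correlation.

`simulate_scale_free_network` is preferential attachment (heavy-tailed,
connected, `m(n − m)` edges). `plant_disease_genes` grows the disease set
with probability `locality` (default 0.8) from the current neighbourhood,
otherwise uniformly, falling back to uniform when the frontier is
exhausted. `plant_key_genes` wires a few non-disease nodes to
`links_per_key` (default 18) distinct disease genes — high-degree,
disease-dominated neighbourhoods, the signature the network statistics
target. `simulate_drugs` gives proximal drugs targets that land inside the
disease set with probability `in_disease_frac` (default 0.5, i.e. drugs
that partly hit disease proteins directly) and otherwise on first
neighbours; random drugs draw uniformly. All generators are deterministic
given their seed, and in the pipeline all stage seeds are derived from the
single configured seed via `SeedSequence` spawn keys.

**What the generator does not emulate:** probe-level microarray noise,
batch structure beyond a mean/scale shift, correlated background genes,
hub-biased disease catalogues, incomplete/noisy interactomes, or drugs
with heterogeneous target counts. Passing recovery tests therefore shows
the chain is correct and well-calibrated under its own assumptions, not
that it would reach the same operating characteristics on real cohorts.

## Numerical choices and degenerate inputs

* Duplicate gene rows collapse by per-cell median at load time (the
  probe-to-gene rule); duplicate sample ids and non-numeric cells are hard
  errors; rows with missing values are dropped and counted.
* Batch handling is per-batch per-gene standardisation (mean 0, sd 1
  within each batch; constant rows zeroed and flagged), declared in output
  metadata. It removes location/scale batch effects only — it is not an
  empirical-Bayes batch moderation and does not borrow strength across
  genes.
* Ties everywhere break deterministically (identifier order); all tables
  use stable sorts.
* Permutation p-values use the plus-one rule and are never 0; empirical
  nulls with σ = 0 yield a flagged NaN z but still report `p_emp`.
* Shortest-path means over empty reachable sets are NaN with a reason;
  isolated candidates are flagged rather than dropped silently.
* Edge-list confidence filtering is off by default (no principled cutoff
  was available); `network_min_score` applies one when given.

## Problem sizes

The default study conditions (400 genes, 16 samples, 400-node network,
50-drug screen, 1000 permutations) run end to end in a few seconds; the
test suite uses reduced permutation counts (100–1000) and graphs of
50–300 nodes so the full suite completes in well under a minute on one
CPU.

## Known limitations

* Unsigned networks only; no biweight midcorrelation; no block-wise
  computation for very large gene sets (tens of thousands of genes will
  be slow and memory-heavy, as the TOM is dense).
* The adaptive static cut resolves well-separated modules but is not a
  full dynamic tree cut; deeply nested module structure may be
  under-split.
* The class-shuffle null conditions on the observed graph; it does not
  model uncertainty in the interactome itself.
* With 8 samples per arm, the rank-sum test on eigengenes has limited
  resolution: at effect size 2 a planted disease module occasionally
  misses the FDR < 0.05 gate. This is a property of the study conditions,
  visible in the disease-module recall reported by
  `scripts/acceptance.py` at some seeds.
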