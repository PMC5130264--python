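# Methods

## The analysis model

The package targets the common design of direct-reprogramming
transcriptomics: a handful of independent case/control comparisons of
the same transition (fibroblast → induced hepatocyte in the motivating
application), each small (2–4 replicates per group), assayed on
different platforms that each miss some genes. Inference at the
single-comparison level is unreliable at these group sizes, so every
conclusion is drawn at the consensus level across comparisons, and the
regulatory interpretation comes from external evidence layers: a
binding-site regulon database for TF → target edges and
protein-interaction tables for complex structure. The package assumes
its inputs are already normalized, gene-level log2 expression matrices;
probe summarization, normalization and batch correction are upstream
concerns.

## Consensus differential expression

Per comparison, the statistic is the difference of group means on the
log2 scale (= log2 fold change) with a two-sample t-test. Two tests are
offered:

* `student` (default) — pooled variance. With 2–4 replicates per group
  the Satterthwaite degrees-of-freedom estimate of the Welch test is so
  noisy that the test becomes visibly conservative (empirical
  false-positive rate ≈ 0.03–0.04 at p < 0.05 under a homoscedastic
  Gaussian null); the pooled test is exact there and its p-values are
  uniform under the null, which the calibration tests require.
* `welch` — unequal variances, for inputs where the homoscedasticity
  assumption is doubtful and calibration matters less than robustness.

Degenerate rows (zero variance in both groups) get p = 1 when the means
agree and the smallest positive double otherwise, so they sort
deterministically instead of propagating NaN. Duplicate gene ids
(probe-level leftovers) collapse to the row with the largest |log2FC|.

A gene is a consensus DEG when four conditions hold (defaults in
parentheses): measured in ≥ `min_present` (4) comparisons; significant —
p < 0.05 and linear |FC| ≥ 1.5 — in ≥ `min_agree` (4) comparisons in any
direction; the same fold-change sign in ≥ `min_agree` of its measured
comparisons with strict majority; and significant calls of the winning
direction strictly outnumbering the opposite ones (exact ties → no
call). Significance and direction are deliberately counted as *separate*
votes: a consistent effect that narrowly misses significance on one
platform still contributes its direction, which is what rescues
genuinely regulated genes in a meta-analysis of underpowered
comparisons. The p < 0.05 filter is the standard one for this design;
the fold-change filter for DEGs is applied for symmetry with the DE-TF
rule and is configurable.

DE-TFs use fold change only: linear |FC| ≥ 1.5 in the same direction in
≥ 3 comparisons, no p filter — regulators act catalytically, so modest
but reproducible shifts are biologically meaningful.

## Regulator enrichment and GRN assembly

Enrichment of a TF's regulon among the DEGs is the one-sided
hypergeometric tail P(X ≥ k) with universe N, annotated regulon size m
and DEG count n. The universe is restricted to genes that were both
measured in ≥ `min_present` comparisons *and* appear in the regulon
database's gene space — genes that could never have been detected or
annotated should not dilute or inflate the test. Benjamini–Hochberg
q-values are reported alongside, but the default decision rule is raw
p < 0.05, the convention of regulon-screening services. An
`include_regulators` override adds named TFs to the network regardless
of the screen (mirroring the practice of manually adding regulators
whose ChIP evidence comes from another organism).

Edges from enriched TFs survive only if the target is a called DEG with
max linear |FC| ≥ 1.5 across comparisons. Nodes carry direction and an
`is_tf` flag; self-loops are allowed when the database asserts
self-regulation. Parallel evidence for the same TF → target pair
collapses to one edge. Degree ranks break ties lexicographically by
gene id so reports are reproducible.

## MCODE

The complex detector follows the canonical three stages. (1) Each
vertex v is weighted by k·d where k is the order of the highest k-core
of v's closed neighborhood and d is that core's density (density without
self-loops, 2|E|/(|V|(|V|−1))). (2) Complexes grow breadth-first from
the highest-weight unvisited seed, admitting neighbors with weight ≥
(1 − vwp)·w(seed); each vertex joins at most one complex; equal-weight
choices resolve lexicographically. (3) A candidate lacking a 2-core is
discarded; haircut (on by default) prunes to the 2-core; fluff (off by
default) optionally adds neighbor shells at a density threshold. Score =
density × size; the significance filter keeps score strictly > 2.
Defaults (vwp = 0.2, haircut on, fluff off) are the published algorithm
defaults; only the score cutoff is fixed by the analysis convention.

## Clustering

Similarity between profiles is the uncentered correlation
s = Σxᵢyᵢ/(‖x‖‖y‖) — the cosine form used by the classic
gene-expression clustering tools; their 1/n factors cancel in the
ratio. Missing entries are handled pairwise-complete; zero-norm
profiles are rejected by name. Agglomeration runs on distance 1 − s via
average linkage by default (single/complete/centroid available; the
linkage used in the motivating analyses is not documented, so this is a
stated choice, not an inference). Exact merge ties follow the
condensed-matrix order, which coincides with smallest-leaf-index order.
Output includes a merge table plus CDT/GTR/ATR files for tree viewers.

## Over-representation statistics

Term enrichment uses the exact two-sided hypergeometric p by the
minimum-likelihood rule — the sum of P(X = j) over all j in the support
with P(X = j) ≤ P(X = k), with a 1 + 1e−9 relative tolerance for
floating-point ties — and Bonferroni step-down (Holm) correction across
the collection. Results order by adjusted p, then overlap size
descending, then term name. Ontology content is an input (any GMT), not
bundled.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for recovery testing. Defaults define the reference
study conditions:

| parameter | default | meaning |
|---|---|---|
| n_datasets | 7 | independent primary-species comparisons |
| replicates_per_group | 3 | samples per group per comparison |
| n_genes | 2000 | gene universe (includes the TFs) |
| n_up_genes / n_down_genes | 250 / 300 | planted up/down programs (the up-program is the smaller, as in observed DEG lists for this transition) |
| n_activator_tfs / n_repressor_tfs / n_decoy_tfs | 5 / 4 / 8 | planted regulators; repressors double as the planted protein complex (a PRC2-like silencing module) |
| regulon_size | (50, 150) | bounds on regulon sizes; activators draw from the upper part (broad programs), repressors from the lower part (focused silenced modules) |
| effect_size | 2.0 | mean |log2FC| of planted genes |
| noise_sd | 0.5 | residual SD on the log2 scale |
| dropout_prob | 0.1 | chance a gene is absent from a platform |
| direction_noise | 0.1 | chance a planted effect flips sign in one dataset, so direction voting is genuinely exercised |
| seed | 42 | root seed |

Baseline expression is Uniform(5, 12) per gene on the log2 scale
(microarray-like intensities, keeps fold changes well defined). Gene
labels are *derived from* regulon construction: each planted gene is
assigned round-robin to one regulon of its class (coverage guaranteed),
regulons are topped up with an 80/20 mix of program/background genes,
and the first regulator of each class gets the largest program (a
master regulator for rank-recovery checks). Planted TFs are themselves
up-shifted, activator regulons include the other planted TFs (giving
the TF–TF core its edges), and every planted TF is guaranteed membership
in at least one regulon (self-regulation in degenerate configs). The
second species is a single mirrored comparison with upper-cased
ortholog symbols (the mouse *Hnf4a* / human *HNF4A* convention); each
planted gene keeps its direction with the requested concordance
probability. The PPI table wires the repressor module into a clique at
confidence ≥ 0.9 over an Erdős–Rényi background whose confidences span
the 0.7 cutoff. All randomness derives from one root seed through fixed
per-purpose stream ids (`default_rng([seed, stream])`), so each piece is
independently reproducible.

Where the motivating study fixes a design quantity (seven comparisons,
the voting thresholds, the 0.7 confidence cutoff, the score > 2 filter,
78% cross-species concordance), the generator's defaults mirror it;
effect and noise magnitudes are not documented anywhere in that design
and are stipulated here once as values a microarray analyst would call
a clear but realistic signal (a 4-SD mean shift).

What the generator does **not** emulate: probe-level effects,
normalization artifacts, batch structure, correlated noise between
genes, RNA-seq counts, and regulon databases with wrong-species or
biased annotation. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated model, not robustness to those
real-data pathologies.

## Problem sizes used by the checks

The bundled checks run the default 2000-gene, 7-comparison study for
recovery; 20 one-thousand-gene studies for decoy-enrichment
calibration; 50 two-hundred-node interactomes with a planted 5-clique
for complex recovery; and a 3000-gene study with 450 + 450 planted
genes for concordance calibration (chosen so that ≥ 500 orthologs
remain evaluable after DE calling in both species). These sizes are the
package's reference configurations and complete in seconds.

## Known limitations

* The consensus vote treats comparisons as exchangeable; there is no
  weighting by study quality or platform coverage.
* Enrichment p-values inherit the regulon database's ascertainment
  biases; the restricted universe mitigates but cannot remove them.
* With `min_agree` close to `n_datasets`, presence dropout dominates
  sensitivity; the presence rule (`min_present`) is a hard gate.
* The MCODE reimplementation follows the published algorithm's default
  variant; scoring variants of fluff mode are not implemented.
* Uncentered correlation is scale-sensitive by design (no centering);
  profiles must be on comparable scales, which holds for log2 fold
  changes but not necessarily for raw intensities across platforms.
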