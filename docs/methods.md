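# Methods

## Problem setting

Gene regulatory network (GRN) inference reconstructs directed
regulator → target relationships from expression data. A persistent failure
mode of expression-based methods is the *cascade error*: for a true chain
A → B → C, the correlation transmitted through B makes A → C look like a
direct interaction. This package implements (i) per-target multiple linear
regression (MLR) as the inference engine, (ii) an explicit detection and
accounting procedure for cascade motifs and cascade errors, (iii) Belsley
collinearity diagnostics for the expression matrix, (iv) subnetwork
extraction for the n ≤ p regime, and (v) a synthetic benchmark generator so
the whole chain is testable without external data.

## Inference model

For each gene g in a G-gene subnetwork with n observations, the package fits

    y_i = β₀ + Σ_j β_j x_ij + ε_i,   i = 1…n,   ε_i ~ N(0, σ²),

where y is gene g's expression and the predictors are all other genes
(optionally restricted to a regulator list). The fit is ordinary least
squares; each predictor gets a two-sided t-test p-value with n − k − 1
residual degrees of freedom. Predictor j with p < α (default α = 0.05, the
conventional significance level; no multiple-testing correction by default,
though Bonferroni/Benjamini-Hochberg are available) yields the called edge
j → g. Every ordered pair is additionally scored 1 − p for ROC ranking.

Two hard preconditions are surfaced as errors rather than worked around:
n ≤ k + 1 (overdefined model — OLS needs more samples than parameters) and
a rank-deficient design (the normal-equations matrix cannot be inverted).
Both are intrinsic MLR limitations and the package reports them as such;
the remedy for the first is subnetwork extraction, not regularisation.

*Known limitation.* OLS is direction-blind: the t statistic of predictor j
in the regression of g equals (up to sign) the partial correlation of the
pair given the remaining genes, which is symmetric. Every true edge
therefore tends to drag its reverse pair — and, through collider
conditioning, co-parent pairs — toward small p-values. On the synthetic
benchmark this caps the achievable AUROC at roughly 0.95 rather than 1.0;
it is a property of the method, not of the implementation.

## Cascade detection and assessment

On a directed edge list, the intermediates are the nodes appearing both as
a regulator and as a target. Edges not incident to an intermediate are
discarded; for each intermediate B, each upstream regulator A is paired
with each downstream target C (A ≠ C; pairs from 2-cycles are excluded,
since self-edges lie outside the G·(G−1) pair universe). The resulting
shortcut pairs are the *cascade motifs*. A pair reachable through several
intermediates is counted once, with all witnesses recorded; the per-case
breakdown (keyed by intermediate) re-counts it in each witness's row.

Assessment enumerates shortcuts on the gold standard: shortcuts that are
themselves gold edges are genuine feed-forward interactions
(`true_cascade`); the remainder are candidate errors, and those present in
the prediction's called-edge set are the cascade errors. Derived
percentages: cascade-error share = 100 · errors / motifs; motif prevalence
= 100 · (motifs − true cascades) / (G·(G−1)). Stored values are exact;
rounding happens only at display time. (For one published subnetwork the
printed prevalence, 0.54 %, differs in the second decimal from the value
its own formula gives, 0.55 %; the formula is implemented as written.)

## Evaluation

AUROC is the Mann-Whitney statistic over the full ranked pair list:
P(random positive outranks random negative), ties ½ via midranks. Edges are
ranked by ascending p-value — the identical ordering to the 1 − p score,
computed on the p scale so that float precision near p = 0 is not
collapsed. Self-pairs are excluded from the universe. Correct/incorrect
prediction counts are |called ∩ gold| and |called \ gold|.

## Collinearity diagnostics

Columns of the design (for expression data: observations × genes) are
scaled to unit Euclidean length, without centering — centering would mask
collinearity involving the constant direction and change the diagnosis. An
SVD gives condition indices η_k = d_max/d_k and variance decomposition
proportions π_jk = (v_jk²/d_k²) / Σ_m (v_jm²/d_m²). Severity bands: CI ≤ 5
none, 5 < CI < 10 weak, 30 < CI < 100 moderate-to-strong, CI ≥ 100 severe;
the published banding leaves 10 ≤ CI ≤ 30 unnamed and the package reports
it as "unclassified" rather than merging it into a neighbour. A component
with large CI and VDP > 0.5 on ≥ 2 variables pinpoints a near-dependency;
large CIs with no concentrated VDP set the fallback finding that the
collinearity involves almost all variables. Exactly singular inputs are
floored at d_max·eps so condition indices stay finite (and astronomically
large, e.g. ~4.5e15 for a duplicated column).

## Subnetwork extraction

Growth starts from a seed vertex (random, or named) and repeatedly adds a
candidate adjacent to the current set, ignoring edge direction. Candidates
are scored by their number of edges to/from the selected set and ranked
descending; the next node is drawn uniformly from the top
⌈fraction · candidates⌉ (ceiling, so the pool is never empty; default
fraction 0.1). Fraction 1.0 is pure random growth; smaller fractions are
increasingly modular. If the frontier empties on a disconnected source,
growth restarts from a fresh random unused vertex. The exact modularity
objective of the original extraction tool is not published; connection
count into the selected set is this package's documented stand-in, chosen
because it preserves the advertised random-to-modular tuning behaviour.

## Synthetic benchmark

`SimulationConfig` defaults define the study conditions: G = 20 genes,
n = 400 observations (safely in the n > p regime), background edge density
0.05 over the topological-order-respecting pairs, 5 vertex-disjoint planted
cascade chains of length 3, edge coefficients uniform in magnitude
0.8–1.2 with random sign, noise σ = 0.2. Source genes are i.i.d. standard
normal per observation; every other gene is its regulators' linear
combination plus Gaussian noise, evaluated in topological order. The
network is acyclic by construction (the expression model is static; cycles
would need a fixed-point solver that is out of scope). Each planted chain's
skip-one shortcut edges are forced absent from the gold standard, so every
benchmark instance contains scorable cascade-error opportunities.

Collinearity injection replaces each listed group's rows post-simulation by
√ρ·z + √(1−ρ)·e mixtures of a shared latent factor z, achieving pairwise
correlation ≈ ρ inside the group (for ρ < 0 only the first member is
anticorrelated with the rest; mutual negative correlation of three or more
variables at a common ρ is not generally realisable). The injection
deliberately overwrites those genes' network signal — it exists to hand the
diagnostics a known near-dependency.

What the generator does *not* emulate: measurement error structure of
microarrays, non-Gaussian expression distributions (a Student-t option
exists for robustness probing), feedback loops, hidden confounders, and
condition-dependent regulation. Passing tests therefore demonstrate
correctness of the machinery and calibration under the model's own
assumptions, not performance on real compendium data, where reported AUROCs
for this family of methods are far lower (≈ 0.5–0.66).

## Numerical and design choices

- p-values are clipped to [0, 1]; constant-expression genes are detected by
  exact zero range (not a variance threshold) and excluded from predictor
  sets with a warning, their pairs scored p = 1.
- Standardisation (per-gene z-scoring) is exposed but off by default; it
  leaves t and p unchanged (affine invariance) and only aids conditioning.
- Prediction files are sorted by ascending p with lexicographic (regulator,
  target) tie-break, making every artefact byte-reproducible; all stages of
  the CLI derive per-stage seeds from one global seed.
- Gold-standard edge files cannot mention isolated genes, so evaluation and
  cascade assessment widen the gold node set to include all predicted
  genes; shortcut enumeration is unaffected by isolated nodes.
- Benchmark problem sizes in tests and the acceptance script (20 seeds of
  the default configuration; 500 null replicates at G = 10, n = 200) were
  chosen as the smallest runs whose Monte-Carlo error is well below the
  effects being checked.

## Calibration results the suite verifies

On null data the edge-call rate matches α within 3 Monte-Carlo standard
errors (500 replicates). On the default benchmark, regression recovers
generative coefficients to well within ±0.15 on average, and end-to-end
AUROC is ≥ 0.90 on every tested seed with mean ≥ 0.95 — far above the 0.5
random-ranking bar, while the gap to 1.0 reflects the direction-blindness
discussed above. AUROC at noise σ = 5 does not exceed AUROC at σ = 0.2;
between σ = 0.2 and σ = 2 the ranking is saturated (true-edge p-values are
essentially zero throughout), so AUROC is flat there rather than falling.
Injected ρ = 0.999 collinearity always produces a condition index above 30,
and an exactly duplicated column is classified severe.
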