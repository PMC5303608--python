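# grncascade

Regression-based gene regulatory network (GRN) inference with explicit
accounting of *cascade errors* — the classic failure mode where an indirect
chain A → B → C is misread as a direct edge A → C — plus Belsley
collinearity diagnostics and a self-contained synthetic benchmark.

The package is aimed at systems-biology practitioners who want to (a) infer
a directed GRN from an expression matrix by per-target multiple linear
regression, (b) quantify how many of the resulting false positives are
cascade errors rather than generic noise, and (c) diagnose the
multicollinearity that destabilises regression on expression data.

## Method in brief

For each gene g with expression vector y over n observations, fit

    y_i = β₀ + Σ_j β_j x_ij + ε_i,   ε_i ~ N(0, σ²),

with every other gene as a predictor. Predictor j with a two-sided t-test
p-value below α (default 0.05) becomes the called edge j → g; all ordered
pairs are scored 1 − p for ROC ranking against a gold standard (AUROC in
Mann-Whitney form, ties ½).

Cascade motifs of a directed network are found by the intermediate-node
procedure: genes appearing in both the regulator and the target column are
the intermediates; pairing each intermediate's regulators with its targets
yields the shortcut pairs A → C. Shortcuts that are not genuine gold-standard
edges, yet are called by the prediction, are the cascade errors:

    cascade error % = 100 · cascade errors / total cascade motifs
    motif prevalence % = 100 · (motifs − true cascades) / (G·(G−1))

Belsley diagnostics scale design columns to unit length and report condition
indices η_k = d_max/d_k with variance decomposition proportions; η ≥ 100 is
severe collinearity, and a large-η component with VDP > 0.5 on two or more
variables pinpoints the genes involved.

Because regression needs n > p, subnetworks are extracted from large gold
standards by seeded growth: start at a random vertex, repeatedly add a
neighbour drawn at random from the top 10 % of candidates ranked by
connections into the current set.

## Worked example

The classic ompR neighbourhood, ten directed edges:

```sh
$ grncascade cascade detect --gold ompr_edges.tsv --out motifs.tsv
[grncascade] 8 cascade motifs -> motifs.tsv
$ head -3 motifs.tsv
regulator	target	witnesses	in_gold
ihfA	bolA	ompR	0
ihfA	fadL	ompR	0
```

ompR is the only gene occurring as both regulator and target, six of the
ten edges touch it, and pairing its two regulators {ihfA, ihfB} with its
four targets {fadL, bolA, ompC, ompF} gives the 8 shortcut pairs — each a
potential cascade error, none a real edge.

End-to-end on synthetic data:

```sh
$ grncascade pipeline --rng-seed 1 --out-dir run/
$ grep -E 'auroc|cascade_errors|max_condition' run/summary.tsv
auroc	0.958534
cascade_errors	0
max_condition_index	40.195489
```

Here the 20-gene benchmark (400 observations, 5 planted cascade chains)
was inferred at α = 0.05 with AUROC 0.959 — well above the 0.5
random-ranking bar — and none of the candidate shortcut pairs was wrongly
called on this seed, while the expression matrix still shows a
moderate-to-strong condition index (40.2), illustrating that collinearity
is present even when inference succeeds.

## Command-line interface

`grncascade {simulate|extract|infer|cascade|evaluate|collinearity|pipeline}`
— every subcommand reads/writes plain TSV, logs to stderr, and is
deterministic given `--rng-seed`. See `--help` per subcommand.

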