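"""Evaluation quantities: possible-edge counts, AUROC, percentage arithmetic.

AUROC is computed in its Mann-Whitney form over the full ranked edge list:
the probability that a uniformly chosen true (gold-standard) edge outranks a
uniformly chosen non-edge, with ties counted one half. Self-pairs are
excluded throughout; the pair universe over G evaluated genes is G*(G-1)
ordered pairs.

All percentage operations return exact values; rounding is a display
concern left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cascade_dce import assess_cascade_errors
from .exceptions import DomainError
from .io_formats import DirectedNetwork, PredictionSet

__all__ = [
    "EvaluationSummary",
    "possible_edges",
    "auroc_from_scores",
    "compute_auroc",
    "cascade_error_pct",
    "cascade_motif_prevalence_pct",
    "percent_correct",
    "summarize",
]


@dataclass(frozen=True)
class EvaluationSummary:
    n_genes: int
    possible_edges: int
    auroc: float
    correct_predictions: int
    incorrect_predictions: int
    total_cascade_motifs: int
    true_cascade: int
    cascade_errors: int
    cascade_error_pct: float
    cascade_motif_prevalence_pct: float


def possible_edges(n_genes: int) -> int:
    """Ordered-pair universe size G * (G - 1) over G tested genes."""
    if n_genes < 1:
        raise DomainError(f"n_genes must be >= 1, got {n_genes}")
    return n_genes * (n_genes - 1)


def auroc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(random positive outranks random negative), ties 1/2.

    Midranks implement the tie-1/2 convention, which makes the statistic
    invariant to strictly monotone score transforms.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError(
            f"AUROC undefined: {n_pos} positives and {n_neg} negatives in the pair universe"
        )
    ranks = rankdata(scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auroc(preds: PredictionSet, gold: DirectedNetwork) -> float:
    """AUROC of the ranked edge list against the gold standard.

    Positives are the gold edges restricted to the scored pair universe;
    every other scored pair is a negative. Edges are ranked by significance
    (ascending p-value) — the same ordering as the 1 - p score, computed on
    the p scale where float precision near zero is not lost.
    """
    p_values = np.array([p for _, _, _, p in preds.scored_edges], dtype=float)
    labels = np.array(
        [(reg, tgt) in gold.edges for reg, tgt, _, _ in preds.scored_edges], dtype=bool
    )
    return auroc_from_scores(-p_values, labels)


def cascade_error_pct(cascade_errors: int, total_motifs: int) -> float:
    """Share of cascade motifs the prediction turned into errors, in percent."""
    if total_motifs <= 0:
        raise DomainError(f"total_motifs must be positive, got {total_motifs}")
    if not 0 <= cascade_errors <= total_motifs:
        raise DomainError(
            f"cascade_errors = {cascade_errors} outside [0, {total_motifs}]"
        )
    return 100.0 * cascade_errors / total_motifs


def cascade_motif_prevalence_pct(
    total_motifs: int, true_cascade: int, possible_edges: int
) -> float:
    """Percentage of the pair universe occupied by spurious shortcut pairs:
    100 * (total motifs - true cascades) / possible edges."""
    if possible_edges <= 0:
        raise DomainError(f"possible_edges must be positive, got {possible_edges}")
    if true_cascade > total_motifs:
        raise DomainError(
            f"true_cascade = {true_cascade} exceeds total_motifs = {total_motifs}"
        )
    return 100.0 * (total_motifs - true_cascade) / possible_edges


def percent_correct(total_relationships: int, wrong_predictions: int) -> float:
    """Percent of relationships predicted correctly: 100 * (total - wrong) / total."""
    if total_relationships <= 0:
        raise DomainError(
            f"total_relationships must be positive, got {total_relationships}"
        )
    if not 0 <= wrong_predictions <= total_relationships:
        raise DomainError(
            f"wrong_predictions = {wrong_predictions} outside [0, {total_relationships}]"
        )
    return 100.0 * (total_relationships - wrong_predictions) / total_relationships


def summarize(preds: PredictionSet, gold: DirectedNetwork) -> EvaluationSummary:
    """Full evaluation of a prediction set against a gold standard."""
    genes = sorted(preds.genes | gold.nodes)
    G = len(genes)
    universe = possible_edges(G)
    auroc = compute_auroc(preds, gold)
    # Edge-list files cannot mention isolated genes, so widen the gold node
    # set to the evaluated universe before the cascade accounting.
    gold_full = DirectedNetwork(gold.nodes | preds.genes, gold.edges, gold.allow_self_loops)
    report = assess_cascade_errors(gold_full, preds)
    correct = len(preds.called_edges & gold.edges)
    incorrect = len(preds.called_edges - gold.edges)
    prevalence = (
        cascade_motif_prevalence_pct(
            report.total_cascade_motifs, report.true_cascade, universe
        )
        if universe > 0
        else 0.0
    )
    err_pct = (
        cascade_error_pct(report.cascade_errors, report.total_cascade_motifs)
        if report.total_cascade_motifs > 0
        else 0.0
    )
    return EvaluationSummary(
        n_genes=G,
        possible_edges=universe,
        auroc=auroc,
        correct_predictions=correct,
        incorrect_predictions=incorrect,
        total_cascade_motifs=report.total_cascade_motifs,
        true_cascade=report.true_cascade,
        cascade_errors=report.cascade_errors,
        cascade_error_pct=err_pct,
        cascade_motif_prevalence_pct=prevalence,
    )
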