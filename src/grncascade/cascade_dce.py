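"""Cascade-motif detection and cascade-error assessment.

A *cascade motif* is the shortcut pair A -> C implied by a two-step chain
A -> B -> C in a directed network. A *cascade error* is a predicted direct
edge A -> C whose only support in the true network is that indirect chain —
the classic failure mode of expression-based network inference, where the
correlation transmitted through B is mistaken for direct regulation.

Detection works on the gold-standard edge list: genes appearing in both the
regulator column and the target column are the intermediates; edges
not incident to an intermediate are discarded; each intermediate's upstream
regulators are paired with its downstream targets to enumerate the shortcut
candidates. A prediction set is then assessed by intersecting its called
edges with the shortcuts that are *not* genuine gold-standard edges.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError
from .io_formats import DirectedNetwork, PredictionSet

__all__ = [
    "CascadeMotifSet",
    "CascadeReport",
    "find_intermediates",
    "filter_retained_edges",
    "enumerate_shortcuts",
    "assess_cascade_errors",
]


@dataclass(frozen=True)
class CascadeMotifSet:
    """Shortcut pairs (A, C) with, per pair, the witness intermediates B."""

    intermediates: frozenset[str]
    retained_edges: frozenset[tuple[str, str]]
    shortcuts: dict[tuple[str, str], frozenset[str]]

    @property
    def n_shortcuts(self) -> int:
        return len(self.shortcuts)

    def shortcuts_via(self, intermediate: str) -> frozenset[tuple[str, str]]:
        """Shortcut pairs witnessed by one intermediate (per-case report row)."""
        return frozenset(
            pair for pair, wits in self.shortcuts.items() if intermediate in wits
        )


@dataclass(frozen=True)
class CascadeReport:
    """Accounting of shortcut pairs against a gold standard and a prediction.

    ``true_cascade`` counts shortcuts that are genuine gold edges
    (true cascades); the remaining shortcuts are ``candidate_errors``, and
    ``cascade_errors`` counts those actually present among the
    prediction's called edges. ``per_case`` breaks the same numbers down by
    intermediate gene; a shortcut with several witnesses appears in each
    witness's row, while the totals count distinct pairs once.
    """

    motifs: CascadeMotifSet
    total_cascade_motifs: int
    true_cascade: int
    candidate_errors: frozenset[tuple[str, str]]
    cascade_errors: int
    erroneous_edges: frozenset[tuple[str, str]]
    per_case: dict[str, dict[str, int]]


def find_intermediates(net: DirectedNetwork) -> frozenset[str]:
    """Nodes present in both edge-list columns: in-degree and out-degree >= 1."""
    return net.regulators() & net.targets()


def filter_retained_edges(net: DirectedNetwork) -> frozenset[tuple[str, str]]:
    """Edges whose regulator or target is an intermediate; the rest are dropped."""
    inter = find_intermediates(net)
    return frozenset(e for e in net.edges if e[0] in inter or e[1] in inter)


def enumerate_shortcuts(net: DirectedNetwork) -> CascadeMotifSet:
    """All shortcut pairs (A, C) with some B such that A -> B and B -> C.

    Degenerate triples are excluded: A != B and B != C hold automatically in
    a self-loop-free network, and A = C pairs (arising from 2-cycles) are
    dropped because self-edges lie outside the G*(G-1) pair universe. A pair
    reachable through several intermediates is counted once, with every
    witness recorded.
    """
    inter = find_intermediates(net)
    shortcuts: dict[tuple[str, str], set[str]] = {}
    for b in inter:
        for a in net.predecessors(b):
            if a == b:
                continue
            for c in net.successors(b):
                if c == b or c == a:
                    continue
                shortcuts.setdefault((a, c), set()).add(b)
    return CascadeMotifSet(
        intermediates=inter,
        retained_edges=filter_retained_edges(net),
        shortcuts={pair: frozenset(w) for pair, w in shortcuts.items()},
    )


def assess_cascade_errors(gold: DirectedNetwork, preds: PredictionSet) -> CascadeReport:
    """Count cascade errors of a prediction against a gold-standard network.

    Shortcuts are enumerated on the *gold* network. Those that are themselves
    gold edges are genuine feed-forward interactions (true cascades); the
    rest are candidate errors, and the ones the prediction calls significant
    are the cascade errors.
    """
    unknown = preds.genes - gold.nodes
    if unknown:
        raise ValidationError(
            f"prediction references genes absent from the gold standard: {sorted(unknown)}"
        )
    motifs = enumerate_shortcuts(gold)
    pairs = frozenset(motifs.shortcuts)
    true_pairs = pairs & gold.edges
    candidate_errors = pairs - gold.edges
    erroneous = candidate_errors & preds.called_edges

    per_case: dict[str, dict[str, int]] = {}
    for b in sorted(motifs.intermediates):
        via = motifs.shortcuts_via(b)
        if not via:
            continue
        per_case[b] = {
            "total_cascade_motifs": len(via),
            "true_cascade": len(via & true_pairs),
            "cascade_errors": len(via & erroneous),
        }

    return CascadeReport(
        motifs=motifs,
        total_cascade_motifs=len(pairs),
        true_cascade=len(true_pairs),
        candidate_errors=candidate_errors,
        cascade_errors=len(erroneous),
        erroneous_edges=erroneous,
        per_case=per_case,
    )
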