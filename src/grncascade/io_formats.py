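"""Tabular I/O: expression matrices, directed edge lists, prediction files.

The canonical in-memory orientation for expression data is genes x
observations (the M3D compendium convention, genes in rows). The regression
layer transposes into observation x predictor design matrices itself, so
exactly one orientation ever exists inside the package.

Edge lists are plain TSV. Two dialects are supported: ``two_column``
(regulator, target per line) and ``gnw_three_column`` (regulator, target,
0/1 label; only label-1 lines are true edges but label-0 endpoints still
enter the node set, matching how GeneNetWeaver gold standards enumerate the
tested pair universe).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "DirectedNetwork",
    "PredictionSet",
    "read_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "write_predictions",
    "read_predictions",
]

PREDICTIONS_HEADER = ("regulator", "target", "score", "p_value")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Continuous expression values, genes in rows, observations in columns."""

    gene_ids: tuple[str, ...]
    observation_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "observation_ids", tuple(self.observation_ids))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.observation_ids)):
            raise ValidationError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.observation_ids)} observations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene identifiers are not unique")
        if len(set(self.observation_ids)) != len(self.observation_ids):
            raise ValidationError("observation identifiers are not unique")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_observations(self) -> int:
        return len(self.observation_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"unknown gene {gene!r}") from None
        return self.values[idx]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(tuple(genes), self.observation_ids, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.observation_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(str(g) for g in frame.index),
            tuple(str(o) for o in frame.columns),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class DirectedNetwork:
    """Directed regulator -> target edges over named nodes.

    Self-loops are rejected unless ``allow_self_loops`` is set; the cascade
    machinery works on the G*(G-1) ordered-pair universe and a self edge has
    no place in it.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    allow_self_loops: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        for reg, tgt in self.edges:
            if reg not in self.nodes or tgt not in self.nodes:
                raise ValidationError(f"edge ({reg!r}, {tgt!r}) has endpoint outside node set")
            if reg == tgt and not self.allow_self_loops:
                raise ValidationError(f"self-loop on {reg!r} is not permitted")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ) -> "DirectedNetwork":
        edges = frozenset(tuple(e) for e in edges)
        nodes = frozenset(extra_nodes) | {n for e in edges for n in e}
        return cls(nodes, edges, allow_self_loops)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def regulators(self) -> frozenset[str]:
        return frozenset(reg for reg, _ in self.edges)

    def targets(self) -> frozenset[str]:
        return frozenset(tgt for _, tgt in self.edges)

    def successors(self, node: str) -> frozenset[str]:
        return frozenset(tgt for reg, tgt in self.edges if reg == node)

    def predecessors(self, node: str) -> frozenset[str]:
        return frozenset(reg for reg, tgt in self.edges if tgt == node)


@dataclass(frozen=True)
class PredictionSet:
    """A ranked edge list plus the subset called significant at ``alpha``.

    ``scored_edges`` holds every ordered gene pair considered, each with a
    ranking score (1 - p) and the raw p-value; ``called_edges`` is exactly the
    p < alpha subset.
    """

    scored_edges: tuple[tuple[str, str, float, float], ...]
    called_edges: frozenset[tuple[str, str]]
    alpha: float
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "scored_edges", tuple(tuple(e) for e in self.scored_edges))
        object.__setattr__(self, "called_edges", frozenset(self.called_edges))
        object.__setattr__(self, "warnings", tuple(self.warnings))
        pairs = set()
        for reg, tgt, _score, p in self.scored_edges:
            if reg == tgt:
                raise ValidationError(f"self-pair ({reg!r}, {reg!r}) in scored edges")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p-value {p} for ({reg!r}, {tgt!r}) outside [0, 1]")
            pairs.add((reg, tgt))
        stray = self.called_edges - pairs
        if stray:
            raise ValidationError(f"called edges not among scored edges: {sorted(stray)}")
        for reg, tgt, _score, p in self.scored_edges:
            if (reg, tgt) in self.called_edges and not p < self.alpha:
                raise ValidationError(
                    f"called edge ({reg!r}, {tgt!r}) has p = {p} >= alpha = {self.alpha}"
                )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for reg, tgt, _, _ in self.scored_edges for g in (reg, tgt))

    def called_network(self, extra_nodes: Iterable[str] = ()) -> DirectedNetwork:
        return DirectedNetwork.from_edges(self.called_edges, extra_nodes=extra_nodes)


def read_expression_matrix(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionMatrix:
    """Read a TSV expression matrix into the canonical genes x observations form.

    The first row holds identifiers for the columns, the first column
    identifiers for the rows; ``orientation`` says whether the rows of the
    *file* are genes or observations. Missing or non-numeric cells are format
    errors — the downstream regression assumes complete design matrices.
    """
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if orientation == "genes_in_columns":
        frame = frame.T
    row_ids = [str(i) for i in frame.index]
    dup = _first_duplicate(row_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    col_ids = [str(c) for c in frame.columns]
    dup = _first_duplicate(col_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate observation id {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        cell = frame.iat[i, j]
        what = "missing value" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        raise FormatError(f"{path}: {what} at gene {row_ids[i]!r}, observation {col_ids[j]!r}")
    return ExpressionMatrix(tuple(row_ids), tuple(col_ids), numeric.to_numpy(dtype=float))


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_edge_list(
    path: str | Path, dialect: str = "gnw_three_column", allow_self_loops: bool = False
) -> DirectedNetwork:
    """Read a directed edge list.

    ``two_column``: every line is an edge; extra numeric trailing fields (as
    written by :func:`write_predictions`) are ignored so prediction files
    round-trip. ``gnw_three_column``: regulator, target, 0/1 label; only
    label-1 lines become edges but every mentioned gene joins the node set.
    A header line is detected when the first line's third field is
    non-numeric.
    """
    if dialect not in ("two_column", "gnw_three_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and len(fields) >= 3 and not _is_number(fields[2]):
                continue  # header
            if dialect == "two_column":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}")
                for extra in fields[2:]:
                    if not _is_number(extra):
                        raise FormatError(
                            f"{path}:{lineno}: trailing field {extra!r} is not numeric"
                        )
                reg, tgt = fields[0], fields[1]
                nodes.update((reg, tgt))
                edges.add((reg, tgt))
            else:
                if len(fields) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
                reg, tgt, label = fields
                if label not in ("0", "1"):
                    raise FormatError(f"{path}:{lineno}: label {label!r} is not 0 or 1")
                nodes.update((reg, tgt))
                if label == "1":
                    edges.add((reg, tgt))
    return DirectedNetwork(frozenset(nodes), frozenset(edges), allow_self_loops)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    """Write edges as two-column TSV, sorted lexicographically (deterministic)."""
    with open(path, "w", encoding="utf-8") as handle:
        for reg, tgt in sorted(net.edges):
            handle.write(f"{reg}\t{tgt}\n")


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    """Write the ranked edge list: ascending p-value, (regulator, target) tie-break."""
    rows = sorted(preds.scored_edges, key=lambda e: (e[3], e[0], e[1]))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(PREDICTIONS_HEADER) + "\n")
        for reg, tgt, score, p in rows:
            handle.write(f"{reg}\t{tgt}\t{score:.10g}\t{p:.10g}\n")


def read_predictions(path: str | Path, alpha: float = 0.05) -> PredictionSet:
    """Read a file written by :func:`write_predictions`; re-derives the called set."""
    path = Path(path)
    scored: list[tuple[str, str, float, float]] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and len(fields) >= 3 and not _is_number(fields[2]):
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            reg, tgt, score_s, p_s = fields
            if not (_is_number(score_s) and _is_number(p_s)):
                raise FormatError(f"{path}:{lineno}: non-numeric score or p-value")
            scored.append((reg, tgt, float(score_s), float(p_s)))
    called = frozenset((r, t) for r, t, _s, p in scored if p < alpha)
    return PredictionSet(tuple(scored), called, alpha)
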