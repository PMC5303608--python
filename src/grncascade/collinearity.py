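"""Belsley collinearity diagnostics: condition indices and variance
decomposition proportions.

Each column of the design matrix is scaled to unit Euclidean length (no
mean-centering — centering would mask collinearity with the intercept and
change the diagnosis). A singular value decomposition X = U D V' of the
scaled matrix gives condition indices eta_k = d_max / d_k; the variance
decomposition proportion of variable j on component k is

    pi_jk = (v_jk^2 / d_k^2) / sum_m (v_jm^2 / d_m^2),

the share of var(b_j) attributable to component k. A component with a large
condition index on which two or more variables place VDP > 0.5 diagnoses a
specific near-dependency; large condition indices with *no* large VDP
indicate a collinearity spread over almost all variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, OverdefinedModelError, ValidationError

__all__ = [
    "CollinearityReport",
    "belsley_diagnostics",
    "classify_ci",
    "flag_involvement",
]

SEVERITY_LEVELS = ("none", "weak", "unclassified", "moderate_to_strong", "severe")


@dataclass(frozen=True)
class CollinearityReport:
    variable_names: tuple[str, ...]
    singular_values: np.ndarray  # descending, length p
    condition_indices: np.ndarray  # ascending, length p, first entry 1
    vdp: np.ndarray  # (p components, p variables); row k = component, col j = variable
    severities: tuple[str, ...]  # per component

    @property
    def p(self) -> int:
        return len(self.variable_names)

    @property
    def max_condition_index(self) -> float:
        return float(self.condition_indices[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per component, condIdx then VDP per variable."""
        frame = pd.DataFrame(self.vdp, columns=list(self.variable_names))
        frame.insert(0, "condIdx", self.condition_indices)
        frame.insert(1, "severity", list(self.severities))
        return frame


def classify_ci(ci: float) -> str:
    """Severity band of one condition index.

    The published bands are 5 < CI < 10 weak, 30 < CI < 100 moderate to
    strong, CI >= 100 severe; CI <= 5 is unremarkable ("none") and the
    10..30 gap between the published bands is reported as "unclassified"
    rather than silently merged into a neighbour.
    """
    if ci < 1:
        raise DomainError(f"condition index must be >= 1, got {ci}")
    if ci <= 5:
        return "none"
    if ci < 10:
        return "weak"
    if ci <= 30:
        return "unclassified"
    if ci < 100:
        return "moderate_to_strong"
    return "severe"


def belsley_diagnostics(
    design: np.ndarray,
    variable_names: Sequence[str] | None = None,
    include_intercept: bool = False,
) -> CollinearityReport:
    """Condition indices and VDPs of a design matrix, columns scaled to unit length.

    ``include_intercept`` appends a constant column before scaling (Belsley's
    original recommendation); off by default because the diagnosis here is
    run directly on expression data matrices whose columns are genes.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValidationError("design must be a 2-D matrix")
    if variable_names is None:
        variable_names = [f"x{j + 1}" for j in range(X.shape[1])]
    names = [str(v) for v in variable_names]
    if len(names) != X.shape[1]:
        raise ValidationError("variable_names length does not match design columns")
    if include_intercept:
        X = np.column_stack([X, np.ones(X.shape[0])])
        names = names + ["intercept"]
    n, p = X.shape
    if p < 2:
        raise ValidationError(f"need at least 2 variables, got {p}")
    if n < p:
        raise OverdefinedModelError(
            f"overdefined design: n = {n} rows < p = {p} columns"
        )
    norms = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValidationError(f"zero-norm column for variable {names[zero[0]]!r}")
    Xs = X / norms

    _, d, Vt = np.linalg.svd(Xs, full_matrices=False)
    # Guard exact singularity: floor at a tiny multiple of d_max so CIs stay finite.
    tiny = d[0] * np.finfo(float).eps
    d_safe = np.maximum(d, tiny)
    # d is descending, so d[0]/d[k] is already ascending with first entry 1;
    # component k of the report is SVD component k throughout.
    condition_indices = d[0] / d_safe
    condition_indices[0] = 1.0

    V = Vt.T  # columns are right singular vectors
    phi = (V ** 2) / (d_safe ** 2)  # (variable j, component k)
    vdp_by_var = phi / phi.sum(axis=1, keepdims=True)
    vdp = vdp_by_var.T  # (component k, variable j)

    severities = tuple(classify_ci(ci) for ci in condition_indices)
    return CollinearityReport(
        variable_names=tuple(names),
        singular_values=d,
        condition_indices=condition_indices,
        vdp=vdp,
        severities=severities,
    )


@dataclass(frozen=True)
class InvolvementFinding:
    """Which variables each large-CI component implicates, plus the fallback flag."""

    diagnosed: dict[int, tuple[str, ...]]  # component index -> involved variables (>= 2)
    large_components: tuple[int, ...]
    diffuse_collinearity: bool  # large CIs present but no component shows big VDPs


def flag_involvement(
    report: CollinearityReport,
    large_ci_cutoff: float = 100.0,
    vdp_cutoff: float = 0.5,
) -> InvolvementFinding:
    """Diagnose collinearity sources: large-CI components with VDP > cutoff on >= 2 variables.

    When large condition indices exist but no component concentrates VDP on
    any variable pair, the near-dependency is diffuse — the collinearity
    appears to involve almost all variables — and the fallback flag is set.
    """
    large = tuple(
        k for k, ci in enumerate(report.condition_indices) if ci >= large_ci_cutoff
    )
    diagnosed: dict[int, tuple[str, ...]] = {}
    for k in large:
        involved = tuple(
            name
            for j, name in enumerate(report.variable_names)
            if report.vdp[k, j] > vdp_cutoff
        )
        if len(involved) >= 2:
            diagnosed[k] = involved
    diffuse = bool(large) and not diagnosed
    return InvolvementFinding(
        diagnosed=diagnosed, large_components=large, diffuse_collinearity=diffuse
    )


def severity_rank(label: str) -> int:
    """Ordinal position of a severity label, for sorting/reporting."""
    try:
        return SEVERITY_LEVELS.index(label)
    except ValueError:
        raise DomainError(f"unknown severity label {label!r}") from None
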