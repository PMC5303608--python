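"""Per-target multiple linear regression and network-wide edge calling.

Each gene in turn is the response; every other gene in the (sub)network is a
predictor. An ordinary-least-squares fit y = b0 + sum_j b_j x_j + e gives a
two-sided t-test p-value per predictor; predictors with p below the
significance level become called regulator -> target edges, and every ordered
pair is scored 1 - p for ROC ranking.

OLS is direction-blind: predictor j significant for target g is reported as
the directed edge j -> g by convention, which is a documented limitation of
the method rather than an inference of causal direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearDesignError, OverdefinedModelError, ValidationError
from .io_formats import ExpressionMatrix, PredictionSet

__all__ = ["RegressionFit", "fit_mlr", "infer_network"]


@dataclass(frozen=True)
class RegressionFit:
    """OLS result for one response gene against k predictor genes."""

    target_gene: str
    predictor_genes: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    residual_df: int
    n_observations: int

    @property
    def k(self) -> int:
        return len(self.predictor_genes)


def fit_mlr(
    response: np.ndarray,
    design: np.ndarray,
    predictor_names: Sequence[str],
    target_gene: str = "y",
) -> RegressionFit:
    """Ordinary least squares of ``response`` on ``[1 | design]``.

    Parameters
    ----------
    response : (n,) vector of observed response values.
    design : (n, k) matrix, one column per predictor gene.
    predictor_names : the k predictor gene names, in column order.

    Raises
    ------
    OverdefinedModelError
        If n <= k + 1: with an intercept there are fewer observations than
        parameters plus one residual degree of freedom, so the model is
        overdefined (n <= p) and OLS is not solvable.
    CollinearDesignError
        If the intercept-augmented design is rank deficient: the normal
        equations matrix cannot be inverted.
    """
    y = np.asarray(response, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    names = tuple(predictor_names)
    if len(names) != k:
        raise ValidationError(f"{k} design columns but {len(names)} predictor names")
    if y.shape[0] != n:
        raise ValidationError("response length does not match design rows")
    if n <= k + 1:
        raise OverdefinedModelError(
            f"overdefined model for target {target_gene!r}: n = {n} observations "
            f"<= p = {k} predictors + intercept; OLS requires more samples than "
            "predictors or the matrix cannot be inverted"
        )
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc) < k + 1:
        raise CollinearDesignError(
            f"collinear design for target {target_gene!r}: rank-deficient "
            "predictor matrix, not invertible"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on tiny residual df
        result = sm.OLS(y, Xc).fit()
    return RegressionFit(
        target_gene=target_gene,
        predictor_genes=names,
        intercept=float(result.params[0]),
        coefficients=np.asarray(result.params[1:], dtype=float),
        standard_errors=np.asarray(result.bse[1:], dtype=float),
        t_statistics=np.asarray(result.tvalues[1:], dtype=float),
        p_values=np.clip(np.asarray(result.pvalues[1:], dtype=float), 0.0, 1.0),
        residual_df=int(result.df_resid),
        n_observations=n,
    )


def infer_network(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    standardize: bool = False,
    regulators: Sequence[str] | None = None,
    correction: str | None = None,
) -> PredictionSet:
    """Fit one regression per target gene and call edges at ``alpha``.

    Every ordered pair (j, g), j != g, receives score = 1 - p_value(j) from
    the regression of g on all other genes; pairs with p < alpha form the
    called edge set. No multiple-testing correction is applied by default (the
    raw 0.05 convention); ``correction`` may be ``"bonferroni"`` or ``"bh"``
    to adjust all p-values jointly before calling.

    ``regulators`` optionally restricts predictor sets to a known regulator
    list (DREAM5-style); by default all subnetwork genes serve as predictors.
    Constant-expression genes are excluded from predictor sets and skipped as
    responses, with a warning record; their pairs are scored p = 1.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    G, n = expr.n_genes, expr.n_observations
    if n < G + 1:
        raise OverdefinedModelError(
            f"cannot regress each gene on the other {G - 1}: n = {n} observations "
            f"< {G + 1} required (n <= p). Extract a smaller subnetwork first."
        )
    values = expr.values
    if standardize:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        values = np.divide(values - mu, sd, out=np.zeros_like(values), where=sd > 0)

    warnings_out: list[str] = []
    spans = np.ptp(values, axis=1)  # exact zero iff every observation identical
    constant = {g for g, span in zip(expr.gene_ids, spans) if span == 0.0}
    for g in sorted(constant):
        warnings_out.append(
            f"gene {g!r} has constant expression; excluded from predictor sets"
        )

    allowed_predictors = set(expr.gene_ids) - constant
    if regulators is not None:
        unknown = set(regulators) - set(expr.gene_ids)
        if unknown:
            raise ValidationError(f"regulators not in matrix: {sorted(unknown)}")
        allowed_predictors &= set(regulators)

    row_of = {g: i for i, g in enumerate(expr.gene_ids)}
    p_by_pair: dict[tuple[str, str], float] = {}
    for g in expr.gene_ids:
        if g in constant:
            continue
        predictors = [h for h in expr.gene_ids if h != g and h in allowed_predictors]
        if not predictors:
            continue
        design = values[[row_of[h] for h in predictors]].T
        fit = fit_mlr(values[row_of[g]], design, predictors, target_gene=g)
        for h, p in zip(predictors, fit.p_values):
            p_by_pair[(h, g)] = float(p)

    pairs = [(a, b) for a in expr.gene_ids for b in expr.gene_ids if a != b]
    raw_p = np.array([p_by_pair.get(pair, 1.0) for pair in pairs])
    if correction is None:
        adj_p = raw_p
    elif correction in ("bonferroni", "bh"):
        method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        adj_p = multipletests(raw_p, method=method)[1]
    else:
        raise ValidationError(f"unknown correction {correction!r}")

    scored = tuple(
        (a, b, 1.0 - p, float(p)) for (a, b), p in zip(pairs, adj_p)
    )
    called = frozenset((a, b) for (a, b), p in zip(pairs, adj_p) if p < alpha)
    return PredictionSet(scored, called, alpha, tuple(warnings_out))
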