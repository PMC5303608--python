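"""Synthetic benchmark: sparse regulatory DAGs with planted cascade chains
and linear-Gaussian expression data.

The generator emulates the setting the inference method targets: a directed,
sparse gene regulatory network whose target genes are linear combinations of
their regulators plus Gaussian noise. Cascade chains A -> B -> C are planted
explicitly and their shortcut edges A -> C are forced *absent* from the gold
standard, so every generated benchmark contains scorable cascade-error
opportunities by construction. The network is acyclic (edges follow a random
topological order): the expression model is a static linear one with no
steady-state solver, so cycles are out of scope.

Optional multicollinearity injection replaces a group of gene rows with
correlated mixtures of a shared latent factor, exercising the Belsley
diagnostics on data whose near-dependency is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import DomainError, ValidationError
from .io_formats import DirectedNetwork, ExpressionMatrix

__all__ = ["SimulationConfig", "generate_network", "simulate_expression", "simulate_benchmark"]


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark conditions.

    Defaults give 20 genes observed 400 times — comfortably more
    observations than predictors, the regime the regression requires — with
    5 planted three-gene cascade chains, background edge density 0.05,
    regulatory effect sizes of order 1 (uniform magnitude in 0.8..1.2,
    random sign) and noise standard deviation 0.2 (strong but not trivial
    signal-to-noise, so edge recovery is good yet imperfect calls remain
    possible).
    """

    n_genes: int = 20
    n_observations: int = 400
    edge_density: float = 0.05
    n_cascade_chains: int = 5
    chain_length: int = 3
    coefficient_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.2
    collinear_groups: tuple[tuple[tuple[str, ...], float], ...] = ()
    heavy_tails: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise DomainError("need at least 3 genes")
        if self.n_observations <= self.n_genes + 1:
            raise DomainError(
                f"n_observations = {self.n_observations} must exceed n_genes + 1 = "
                f"{self.n_genes + 1} for the regression to be solvable"
            )
        if not 0.0 <= self.edge_density < 1.0:
            raise DomainError("edge_density must lie in [0, 1)")
        if self.chain_length < 3:
            raise DomainError("chain_length must be >= 3")
        if self.n_cascade_chains < 0:
            raise DomainError("n_cascade_chains must be >= 0")
        low, high = self.coefficient_range
        if not 0.0 < low <= high:
            raise DomainError("coefficient_range must satisfy 0 < low <= high")
        if self.noise_sd <= 0.0:
            raise DomainError("noise_sd must be positive")
        for genes, rho in self.collinear_groups:
            if not -1.0 < rho < 1.0:
                raise DomainError(f"collinear correlation {rho} outside (-1, 1)")
            if len(genes) < 2:
                raise DomainError("collinear group needs >= 2 genes")


def _gene_names(G: int) -> list[str]:
    width = len(str(G))
    return [f"G{i + 1:0{width}d}" for i in range(G)]


def generate_network(
    config: SimulationConfig,
) -> tuple[DirectedNetwork, dict[tuple[str, str], float]]:
    """Random DAG with planted cascade chains and per-edge coefficients.

    Nodes receive a random topological order; background edges respect that
    order at ``edge_density``. Each planted chain occupies ``chain_length``
    consecutive draws of order-distinct vertices; its step edges are forced
    present and each skip-one shortcut along it is forced absent from the
    gold standard, so the chain contributes candidate cascade errors.
    """
    rng = np.random.default_rng(config.rng_seed)
    G = config.n_genes
    if config.n_cascade_chains * config.chain_length > G:
        raise DomainError(
            f"{config.n_cascade_chains} chains of length {config.chain_length} "
            f"need more vertices than the {G} available (chains are vertex-disjoint)"
        )
    names = _gene_names(G)
    order = rng.permutation(G)  # order[i] = topological position of gene i
    position = {names[i]: int(order[i]) for i in range(G)}
    by_position = sorted(names, key=lambda g: position[g])

    edges: set[tuple[str, str]] = set()
    for i in range(G):
        for j in range(i + 1, G):
            if rng.random() < config.edge_density:
                edges.add((by_position[i], by_position[j]))

    forbidden: set[tuple[str, str]] = set()
    free = list(range(G))
    for _ in range(config.n_cascade_chains):
        picks = sorted(rng.choice(len(free), size=config.chain_length, replace=False))
        chain = [by_position[free[p]] for p in picks]
        for p in sorted(picks, reverse=True):
            free.pop(p)
        for a, b in zip(chain, chain[1:]):
            edges.add((a, b))
        for a, c in zip(chain, chain[2:]):  # skip-one shortcuts forced absent
            forbidden.add((a, c))
    edges -= forbidden

    low, high = config.coefficient_range
    coefficients = {
        e: float(rng.uniform(low, high) * rng.choice((-1.0, 1.0)))
        for e in sorted(edges)
    }
    net = DirectedNetwork(frozenset(names), frozenset(edges))
    return net, coefficients


def simulate_expression(
    net: DirectedNetwork,
    coefficients: dict[tuple[str, str], float],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Linear-Gaussian expression: sources ~ N(0, 1); every other gene is
    sum_j beta_j * regulator_j + eps, eps ~ N(0, noise_sd^2), evaluated in
    topological order."""
    graph = nx.DiGraph()
    graph.add_nodes_from(net.nodes)
    graph.add_edges_from(net.edges)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValidationError("expression simulation requires an acyclic network")
    missing = set(net.edges) - set(coefficients)
    if missing:
        raise ValidationError(f"edges lacking coefficients: {sorted(missing)}")

    rng = np.random.default_rng(config.rng_seed + 1)
    n = config.n_observations
    genes = sorted(net.nodes)
    rows = {g: np.zeros(n) for g in genes}

    def noise(scale: float) -> np.ndarray:
        if config.heavy_tails:
            return scale * rng.standard_t(df=3, size=n) / np.sqrt(3.0)
        return rng.normal(0.0, scale, size=n)

    for g in nx.lexicographical_topological_sort(graph):
        regulators = sorted(net.predecessors(g))
        if not regulators:
            rows[g] = noise(1.0)
        else:
            signal = sum(coefficients[(r, g)] * rows[r] for r in regulators)
            rows[g] = signal + noise(config.noise_sd)

    values = np.stack([rows[g] for g in genes])
    values = _inject_collinearity(values, genes, config, rng)
    obs_ids = tuple(f"obs{i + 1}" for i in range(n))
    return ExpressionMatrix(tuple(genes), obs_ids, values)


def _inject_collinearity(
    values: np.ndarray,
    genes: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replace each collinear group's rows by sqrt(rho)*z + sqrt(1-rho)*e mixtures.

    z is one latent standard-normal factor per group, e fresh independent
    noise per member, so every within-group pair has correlation ~ rho. The
    injection overwrites the network-derived signal of those genes — it
    exists to hand the collinearity diagnostics a known near-dependency, not
    to preserve edge recoverability for the affected genes.
    """
    if not config.collinear_groups:
        return values
    values = values.copy()
    index = {g: i for i, g in enumerate(genes)}
    n = values.shape[1]
    for members, rho in config.collinear_groups:
        unknown = [g for g in members if g not in index]
        if unknown:
            raise ValidationError(f"collinear group references unknown genes: {unknown}")
        z = rng.normal(size=n)
        sign = np.sign(rho) if rho != 0 else 1.0
        a = np.sqrt(abs(rho))
        b = np.sqrt(1.0 - abs(rho))
        for m, g in enumerate(members):
            flip = sign if (m > 0 and sign < 0) else 1.0
            values[index[g]] = flip * a * z + b * rng.normal(size=n)
    return values


def simulate_benchmark(
    config: SimulationConfig,
) -> tuple[DirectedNetwork, dict[tuple[str, str], float], ExpressionMatrix]:
    """Generate gold standard, coefficients and expression in one call."""
    net, coeffs = generate_network(config)
    expr = simulate_expression(net, coeffs, config)
    return net, coeffs, expr
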