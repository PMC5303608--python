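import numpy as np
import pytest

from grncascade import DirectedNetwork, ExpressionMatrix

# The ten printed regulator -> target rows of the E. coli worked example
# (ompR operon neighbourhood) used throughout the cascade tests.
WORKED_EXAMPLE_EDGES = (
    ("hupB", "tyrP"),
    ("crp", "hupA"),
    ("narL", "dmsB"),
    ("narL", "dmsC"),
    ("ihfA", "ompR"),
    ("ihfB", "ompR"),
    ("ompR", "fadL"),
    ("ompR", "bolA"),
    ("ompR", "ompC"),
    ("ompR", "ompF"),
)

RETAINED_EXAMPLE_EDGES = frozenset(
    [
        ("ihfA", "ompR"),
        ("ihfB", "ompR"),
        ("ompR", "fadL"),
        ("ompR", "bolA"),
        ("ompR", "ompC"),
        ("ompR", "ompF"),
    ]
)

EXPECTED_SHORTCUTS = frozenset(
    (a, c) for a in ("ihfA", "ihfB") for c in ("fadL", "bolA", "ompC", "ompF")
)


@pytest.fixture
def worked_example_network() -> DirectedNetwork:
    return DirectedNetwork.from_edges(WORKED_EXAMPLE_EDGES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_expression(values: np.ndarray, prefix: str = "g") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = tuple(f"{prefix}{i + 1}" for i in range(values.shape[0]))
    obs = tuple(f"obs{j + 1}" for j in range(values.shape[1]))
    return ExpressionMatrix(genes, obs, values)
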