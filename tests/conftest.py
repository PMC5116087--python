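import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ipanda.io import ExpressionMatrix
from ipanda.topology import ACTIVATION, PathwayGraph, PathwayUnit

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_graph(pathway_id, nodes, edges, signs=None):
    """Build a pathway graph from single-gene node names and edge pairs."""
    signs = signs or {}
    units = {n: PathwayUnit(n, (n,), signs.get(n, +1)) for n in nodes}
    return PathwayGraph(
        pathway_id, units, [(a, b, ACTIVATION) for a, b in edges]
    )


@pytest.fixture
def diamond():
    """A -> {B, C} -> D: the canonical two-walk worked example."""
    return make_graph(
        "diamond", "ABCD", [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
    )


def expr(values: dict, samples: list[str], scale="log2", dataset_id="ds1"):
    """Expression matrix from {gene: [per-sample values]}."""
    return ExpressionMatrix(
        pd.DataFrame.from_dict(values, orient="index", columns=samples).astype(
            float
        ),
        scale=scale,
        dataset_id=dataset_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
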