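import warnings

import numpy as np
import pytest

from modulenet import coexpr, synth
from modulenet.io import CASE, CONTROL, ExpressionMatrix

# the documented default study conditions: 4 planted modules x 50 genes,
# 200 background genes, 8+8 samples, effect 2, loading 0.8, noise 0.6
DEFAULT_FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def default_fixture():
    expr, truth = synth.simulate_expression(seed=DEFAULT_FIXTURE_SEED)
    return expr, truth


@pytest.fixture(scope="session")
def detected_modules(default_fixture):
    """Soft threshold -> TOM -> modules on the default fixture (shared)."""
    expr, truth = default_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = coexpr.pick_soft_threshold(expr)
        matrices = coexpr.build_matrices(expr, report.chosen_power)
        partition, eigengenes = coexpr.detect_modules(matrices, expr)
    return report, matrices, partition, eigengenes


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples, hand-sized for arithmetic checks."""
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3", "G4"],
        sample_ids=[f"S{i}" for i in range(6)],
        values=rng.normal(size=(4, 6)),
        condition=[CASE] * 3 + [CONTROL] * 3,
    )
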