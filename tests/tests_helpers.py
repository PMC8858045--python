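import numpy as np

from modulenet.io import CASE, CONTROL, ExpressionMatrix


def make_separable_expression(n_per_class=8, effect=5.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    shift = np.array([effect] * n_per_class + [0.0] * n_per_class)
    values = shift + rng.normal(scale=0.3, size=(2, n))
    return ExpressionMatrix(
        gene_ids=["P0", "P1"],
        sample_ids=[f"S{i}" for i in range(n)],
        values=values,
        condition=[CASE] * n_per_class + [CONTROL] * n_per_class,
    )
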