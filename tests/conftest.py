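import numpy as np
import pytest

from subnetmark.data_io import ExpressionMatrix
from subnetmark.synthetic import SyntheticSpec, gen_expression, gen_ppi


@pytest.fixture
def small_expr():
    """4 genes x 6 samples (3 case / 3 control) with hand-set values."""
    values = np.array(
        [
            [5.0, 5.2, 4.8, 3.0, 3.1, 2.9],   # up in cases, ~2 log2 units
            [3.0, 2.9, 3.1, 5.0, 5.1, 4.9],   # down in cases
            [7.0, 7.1, 6.9, 7.0, 6.9, 7.1],   # null
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],   # null, varying
        ]
    )
    samples = ["T1", "T2", "T3", "N1", "N2", "N3"]
    labels = {s: ("case" if s.startswith("T") else "control") for s in samples}
    return ExpressionMatrix(["UPG", "DOWNG", "FLATG", "VARG"], samples, values, labels)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(rng_seed=11)


@pytest.fixture(scope="session")
def synthetic_study(default_spec):
    """Expression + truth + planted graph + CNA list under default conditions."""
    expr, truth = gen_expression(default_spec)
    edges, blocks, cna = gen_ppi(default_spec, truth)
    return {"expr": expr, "truth": truth, "edges": edges, "blocks": blocks, "cna": cna}
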