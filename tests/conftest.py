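import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from herdclust.survey import TypedSurvey, VariableSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20210526)


def random_mixed_survey(rng, n_herds=10, n_quant=3, n_qual=4, missing_rate=0.0):
    """Small random mixed-type survey for property tests."""
    cols, specs = {}, []
    for q in range(n_quant):
        cols[f"q{q}"] = rng.normal(size=n_herds)
        specs.append(VariableSpec(f"q{q}", "quantitative"))
    kinds = ["nominal", "binary_symmetric", "binary_asymmetric", "ordinal"]
    for j in range(n_qual):
        kind = kinds[j % len(kinds)]
        if kind == "ordinal":
            levels = ("lo", "mid", "hi")
            cols[f"c{j}"] = rng.choice(levels, n_herds)
            specs.append(VariableSpec(f"c{j}", kind, levels))
        elif kind.startswith("binary"):
            cols[f"c{j}"] = rng.integers(0, 2, n_herds)
            specs.append(VariableSpec(f"c{j}", kind, (0, 1)))
        else:
            cols[f"c{j}"] = rng.choice(list("abc"), n_herds)
            specs.append(VariableSpec(f"c{j}", kind))
    values = pd.DataFrame(cols, index=[f"h{i}" for i in range(n_herds)])
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = values.mask(mask)
    return TypedSurvey(values, specs)


@pytest.fixture
def mixed_survey(rng):
    return random_mixed_survey(rng)
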