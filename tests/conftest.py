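import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import singlebud as sb

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_table():
    """One default synthetic study dataset, detection-filtered."""
    design = sb.study_design(seed=7)
    table, truth = sb.generate_expression(design)
    filtered, dropped = sb.filter_undetected_genes(table, 0.5)
    assert dropped == ["DAM2-like"]
    return filtered, truth


@pytest.fixture()
def tiny_table():
    """Hand-built 8-bud, 2-gene table across two stages."""
    values = pd.DataFrame(
        {"gA": [1.0, 2.0, 3.0, 4.0, 2.0, 4.0, 6.0, 8.0],
         "gB": [4.0, 3.0, 2.0, 1.0, 8.0, 6.0, 4.0, 2.0]},
        index=[f"b{i}" for i in range(8)],
    )
    stages = pd.Series(["S1"] * 4 + ["S2"] * 4, index=values.index)
    return sb.ExpressionTable(values, stages)


@pytest.fixture(scope="session")
def dip_null_71():
    return sb.dip_null_table(71, 1000, np.random.default_rng(424242))
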