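import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crvi_bmd as cb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rat_design() -> cb.DoseDesign:
    """The study layout: 6 dose groups x 3 replicates (rats skip 14 mg/L)."""
    return cb.default_design()


@pytest.fixture()
def small_matrix() -> cb.ExpressionMatrix:
    data = pd.DataFrame(
        [[100.0, 110.0, 200.0], [50.0, 55.0, 60.0], [10.0, 12.0, 11.0]],
        index=["p1", "p2", "p3"], columns=["s1", "s2", "s3"],
    )
    return cb.ExpressionMatrix(data)


def make_two_group_matrix(ctrl_vals, exp_vals, n_null=0, seed=0):
    """Expression matrix + design with one control and one exposed group."""
    rng = np.random.default_rng(seed)
    n_c, n_e = len(ctrl_vals), len(exp_vals)
    probes = {"probe_signal": list(ctrl_vals) + list(exp_vals)}
    for i in range(n_null):
        probes[f"null_{i:04d}"] = list(2.0 ** rng.normal(8, 0.25, n_c + n_e))
    samples = [f"c{i}" for i in range(n_c)] + [f"e{i}" for i in range(n_e)]
    data = pd.DataFrame(probes, index=samples).T
    matrix = cb.ExpressionMatrix(data)
    design = cb.DoseDesign(pd.DataFrame({
        "sample_id": samples,
        "sdd_mgL": [0.0] * n_c + [520.0] * n_e,
        "cr6_ppm": [0.0] * n_c + [181.5] * n_e,
        "timepoint": "day91", "species": "rat",
    }))
    return matrix, design
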