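import numpy as np
import pandas as pd
import pytest

import endotype as et


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    cfg = et.SimConfig(n_patients=150, seed=42)
    clinical, counts, muts, segs, truth = et.generate_cohort(cfg)
    return {
        "config": cfg,
        "clinical": clinical,
        "counts": counts,
        "mutations": muts,
        "segments": segs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    return et.log2_normalized(small_cohort["counts"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_norm():
    """Hand-sized normalized matrix with the special signature genes."""
    values = pd.DataFrame(
        {
            "S1": [13.0, 6.0, 6.0, 8.0, 9.0],
            "S2": [11.0, 8.0, 6.0, 7.0, 6.0],
            "S3": [12.0, 5.0, 5.0, 9.0, 8.0],
        },
        index=["ESR1", "HOXB13", "IL17BR", "G1", "G2"],
    )
    sf = pd.Series(1.0, index=values.columns)
    return et.NormalizedMatrix(values=values, size_factors=sf)
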