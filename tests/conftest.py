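import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from icmfate.synthetic_data import (
    SyntheticSpec,
    embryo_preset,
    generate_cohort,
    generate_specimen,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_organoid():
    """One ~120-cell organoid-like specimen with ground-truth labels."""
    spec = SyntheticSpec(
        n_cells=120,
        ball_radius=32.0,
        fate_rule={"DP": 0.10, "DN": 0.25, "EPI": 0.30, "PRE": 0.35},
        seed=11,
    )
    return generate_specimen(spec, specimen_id="org-small")


@pytest.fixture(scope="session")
def embryo_cohort():
    """Six embryo-mode specimens (ICM + TE shell) with lineage labels."""
    return generate_cohort(embryo_preset("mid"), n_specimens=6, seed=5, prefix="emb")
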