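import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import scisomir as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref6():
    return sc.make_reference(6, seed=11)


@pytest.fixture(scope="session")
def ref20():
    return sc.make_reference(20, seed=5)


@pytest.fixture(scope="session")
def mixed_sim(ref20):
    """4 cells x 2000 molecules over all five categories, no UMI/adapter/PCR,
    so reads are the bare inserts and read-level == molecule-level truth."""
    cfg = sc.SimulationConfig(
        n_cells=4, reads_per_cell=2000, seed=2,
        pcr_duplication_mean=1.0, umi_length=0, adapter="",
    )
    return sc.simulate_cells(ref20, cfg)


@pytest.fixture(scope="session")
def mixed_frame(mixed_sim):
    t = mixed_sim.truth.molecules
    return pd.DataFrame(
        {
            "cell": t["cell"].to_numpy(),
            "read_id": [f"{c}|m{m}" for c, m in zip(t["cell"], t["molecule"])],
            "seq": t["insert"].to_numpy(),
            "umi": "",
        }
    )


@pytest.fixture(scope="session")
def mixed_ann(mixed_frame, ref20):
    ann, _ = sc.annotate_frame(mixed_frame, ref20)
    return ann
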