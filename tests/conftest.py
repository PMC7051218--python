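import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evrepro import AbundanceTable, Flavor, SyntheticConfig, build_design, derive_grouping, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def design33():
    return build_design(3, 3)


@pytest.fixture
def tr_grouping(design33):
    return derive_grouping(design33, "TR")


@pytest.fixture
def br_grouping(design33):
    return derive_grouping(design33, "BR")


@pytest.fixture
def small_apex_table():
    """4 proteins x 9 replicates, all complete cases, mild variation."""
    rng = np.random.default_rng(42)
    values = rng.lognormal(10, 0.3, (4, 9))
    return AbundanceTable(
        protein_ids=tuple(f"P{i}" for i in range(4)),
        replicate_ids=tuple(f"R{j + 1}" for j in range(9)),
        values=values,
        flavor=Flavor.APEX,
    )


@pytest.fixture
def synthetic_dataset():
    cfg = SyntheticConfig(n_proteins=300, seed=7)
    lfq, apex, design, truth = generate(cfg)
    return cfg, lfq, apex, design, truth
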