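import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import intervalcorr as ic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def space():
    return ic.GenomeSpace({"chrA": 1000, "chrB": 500})


@pytest.fixture
def mb_space():
    return ic.GenomeSpace({"chr1": 1_000_000})


def make_fs(chrom_intervals: dict, label: str = "") -> ic.FeatureSet:
    return ic.FeatureSet(
        {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in chrom_intervals.items()},
        label=label,
    )


@pytest.fixture
def fs_factory():
    return make_fs
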