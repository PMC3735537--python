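import numpy as np
import pytest
from hypothesis import settings

import circasense as cs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return cs.SamplingDesign()


@pytest.fixture(scope="session")
def band():
    return cs.PeriodBand()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_dataset(rng, n_probes=4, n_replicates=2, design=None):
    """Small random dataset with raw replicate rows (helper, not a fixture)."""
    design = design or cs.SamplingDesign()
    tcs = []
    for i in range(n_probes):
        direction = "sense" if i % 2 == 0 else "antisense"
        tcs.append(
            cs.ProbeTimeCourse(
                probe_id=f"p{i}",
                sas_id=f"s{i // 2}",
                direction=direction,
                replicate_values=rng.normal(size=(n_replicates, design.n_timepoints)),
                replicate_flags=rng.random((n_replicates, design.n_timepoints)) < 0.9,
            )
        )
    return cs.ExpressionDataset(design=design, timecourses=tcs)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by pipeline-level tests."""
    cfg = cs.SimulationConfig(seed=11, n_sense=120, n_antisense=60)
    return cs.simulate_dataset(cfg)
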