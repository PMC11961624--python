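import numpy as np
import pytest

from coroscreen.model import TrainConfig, cases_to_tensors, train_task
from coroscreen.nn import NetworkConfig
from coroscreen.phantom import PhantomConfig, generate_cohort_records, generate_phantom
from coroscreen.pipeline import DEFAULT_CLASS_MIX
from coroscreen.preprocess import PreprocessConfig

ALL_ANOMALIES = [(cls, course)
                 for cls in ("R-AAOCA", "L-AAOCA")
                 for course in ("interarterial", "prepulmonic", "retroaortic",
                                "high_takeoff", "subpulmonic")]


@pytest.fixture(scope="session")
def normal_record():
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def anomalous_records():
    """One generated case per (vessel, course) combination."""
    return {
        (cls, course): generate_phantom(
            PhantomConfig(anomaly_class=cls, course=course, seed=21))
        for cls, course in ALL_ANOMALIES
    }


@pytest.fixture(scope="session")
def small_cohort():
    """40 mixed cases at the default phantom resolution."""
    return generate_cohort_records(40, DEFAULT_CLASS_MIX, seed=909)


@pytest.fixture(scope="session")
def small_tensor_cases(small_cohort):
    return cases_to_tensors(small_cohort, PreprocessConfig(target_dims=(24, 24, 16)))


@pytest.fixture(scope="session")
def trained_tiny(small_tensor_cases):
    """A one-member anomaly model trained briefly on the small cohort."""
    net = NetworkConfig.tiny((24, 24, 16))
    cfg = TrainConfig(total_epochs=10, n_members=1, seed=5, patience=20)
    return train_task(small_tensor_cases, "anomaly", net, cfg)
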