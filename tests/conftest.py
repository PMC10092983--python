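import numpy as np
import pytest

from ddmrd import AmplitudeModel, WellSpec
from ddmrd.containers import ClassifiedWell
from ddmrd.simulate import simulate_control_wells


@pytest.fixture(scope="session")
def well_spec():
    return WellSpec()


@pytest.fixture(scope="session")
def small_spec():
    """A smaller well for tests where droplet count is not the point."""
    return WellSpec(n_droplets=2000)


@pytest.fixture(scope="session")
def model1():
    return AmplitudeModel.default(["t1"])


@pytest.fixture(scope="session")
def model3():
    return AmplitudeModel.default(["lo", "mid", "hi"])


@pytest.fixture(scope="session")
def gates1(model1, small_spec):
    from ddmrd import derive_gates

    controls = simulate_control_wells(["t1"], model1, small_spec, seed=42)
    return derive_gates(controls, ["t1"])


def make_classified(k, n, target="t1", well_id="W01", gates_id="g", role="sample",
                    sample_id="s", **kw):
    """A ClassifiedWell with k target positives of n droplets, rest empty."""
    counts = {
        "empty": n - k,
        "reference_only": 0,
        "unassigned": 0,
        f"target_only:{target}": k,
        f"target_and_reference:{target}": 0,
    }
    return ClassifiedWell(
        well_id=well_id, sample_id=sample_id, role=role, counts=counts,
        total_droplets=n, gates_id=gates_id, **kw,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230325)
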