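import numpy as np
import pytest

import megscenes as m


@pytest.fixture(scope="session")
def layout102():
    return m.make_sensor_layout(102)


@pytest.fixture(scope="session")
def default_subject(layout102):
    """One fully simulated and preprocessed subject under the default
    scenario, with its four cross-decoding matrices (shared across tests
    because simulation dominates runtime)."""
    config = m.SimulationConfig(seed=1)
    data = m.simulate_subject(config, layout102, subject_index=0)
    pp = m.PreprocessConfig()
    localizer = m.preprocess_subject(*data["localizer"], layout102, pp)
    main = m.preprocess_subject(*data["main"], layout102, pp)
    matrices = m.cross_decode_subject(localizer, main)
    return {
        "raw": data,
        "localizer": localizer,
        "main": main,
        "matrices": matrices,
    }


def tiny_design(
    n_conditions=1,
    trials=5,
    onebacks=0,
    n_runs=1,
    n_exemplars=5,
    categories=("indoor", "outdoor"),
):
    """Minimal ExperimentDesign for unit tests."""
    conditions = []
    exemplars = {}
    for c in range(n_conditions):
        for cat in categories:
            key = (f"cond{c}", cat)
            conditions.append(key)
            exemplars[key] = [f"{cat}_{c}_{e}" for e in range(n_exemplars)]
    return m.ExperimentDesign(
        experiment_name="tiny",
        conditions=conditions,
        exemplars=exemplars,
        n_runs=n_runs,
        trials_per_condition_per_run=trials,
        onebacks_per_run=onebacks,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
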