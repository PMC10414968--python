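import numpy as np
import pytest

from gravframe import ExperimentGeometry, PopulationSpec, simulate_population


@pytest.fixture(scope="session")
def body_geom() -> ExperimentGeometry:
    """Default body-tilt design: ±25° tilts, 6° counter-roll, 9 orientations."""
    return ExperimentGeometry()


@pytest.fixture(scope="session")
def horizon_geom() -> ExperimentGeometry:
    """Cue-conflict design: the depicted horizon tilts ±25°, observer upright."""
    return ExperimentGeometry(mode="horizon_tilt")


@pytest.fixture(scope="session")
def half_half_population(body_geom):
    """200 neurons, half gravity-anchored and half retina-anchored, SNR 10."""
    spec = PopulationSpec(
        n_neurons=200,
        proportions={"gravitational": 0.5, "retinal": 0.5, "mixed": 0.0, "untuned": 0.0},
        noise_model="gaussian",
        amplitude_range=(40.0, 40.0),
        sigma_range=(4.0, 4.0),
    )
    trials, truth = simulate_population(spec, body_geom, np.random.default_rng(11))
    return trials, truth
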