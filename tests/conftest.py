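import dataclasses

import numpy as np
import pytest

import optoacid as oa


@pytest.fixture(scope="session")
def fig1_protocol():
    """0.5-s stim / 1-s image interleaved for 150 s, then 150 s recovery."""
    return oa.build_protocol(0.5, 1.0, 150.0, 150.0)


@pytest.fixture(scope="session")
def soma():
    return oa.CompartmentGeometry("sphere", 7.5)


@pytest.fixture(scope="session")
def phys():
    return oa.PhysiologyParams()


@pytest.fixture(scope="session")
def sensor():
    return oa.SensorParams()


@pytest.fixture(scope="session")
def cheriff_trace(fig1_protocol, soma, phys, sensor):
    """One CheRiff-like simulated cell under the canonical protocol."""
    return oa.simulate_cell(soma, oa.CHERIFF_LIKE, sensor, phys,
                            fig1_protocol, seed=11, dt=1e-3)


@pytest.fixture(scope="session")
def control_trace(fig1_protocol, soma, phys, sensor):
    """Opsin-negative control (f_H = 0): artifact only, constant pH."""
    opsin = dataclasses.replace(oa.CHERIFF_LIKE, f_H=0.0)
    return oa.simulate_cell(soma, opsin, sensor, phys, fig1_protocol,
                            seed=12, dt=1e-3)


@pytest.fixture(scope="session")
def fine_calibration(sensor):
    """Finely stepped (0.1-pH) calibration from the sensor model, used
    when validating pipeline parameter recovery so that calibration
    interpolation error does not confound the measurement."""
    from optoacid.io import calibration_pairs_from_sensor
    knots = np.round(np.arange(6.4, 7.31, 0.1), 2)
    return oa.build_calibration(calibration_pairs_from_sensor(sensor, knots))


@pytest.fixture(scope="session")
def sensor_calibration(sensor):
    """Calibration knots sampled from the sensor model at the measured
    buffer steps 6.4-7.3."""
    from optoacid.io import calibration_pairs_from_sensor
    return oa.build_calibration(calibration_pairs_from_sensor(sensor))


def dff_of(trace):
    """dF/F of a simulated trace relative to its first sample."""
    return (trace.F - trace.F[0]) / trace.F[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
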