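import numpy as np
import pytest

from silkflight import (
    BodyKinematics,
    FourierWaveform,
    MothConfiguration,
    WingKinematics,
    build_strips,
)
from silkflight.synth import SynthSpec, synth_moth, synth_near_trim_moth


def steady_translation_config(
    alpha_deg: float = 45.0,
    V: float = 2.0,
    chord: float = 0.02,
    R: float = 0.1,
    n_strips: int = 200,
    f: float = 10.0,
    rho: float = 1.225,
) -> MothConfiguration:
    """Rectangular wing held rigid (all waveforms constant) translating
    at speed V along -airflow: a closed-form fixed-incidence oracle case
    where the angle of attack equals the feathering angle."""
    const = lambda v: FourierWaveform.constant(v, f)
    wing = WingKinematics(
        phi=const(0.0), theta=const(0.0), alpha=const(alpha_deg),
        beta=const(0.0), betar=0.0, f=f,
    )
    body = BodyKinematics(chi=const(0.0), u=const(V), w=const(0.0))
    morph = build_strips(lambda r: np.full_like(r, chord), R=R, n_strips=n_strips)
    return MothConfiguration(morph=morph, wing_kin=wing, body_kin=body,
                             mt=2e-3, rho=rho)


@pytest.fixture(scope="session")
def luna_moth():
    """One synthetic moth drawn inside the A. luna parameter bounds."""
    return synth_moth(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def near_trim_moth():
    """A synthetic moth tuned onto force/moment equilibrium."""
    return synth_near_trim_moth(SynthSpec(seed=1))
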