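import pytest

from breathmech import RunConfig
from breathmech.simulate import (Artefacts, SimScenario, Trajectory,
                                 simulate_protocol)


def make_scenario(E=25.0, R=5.0, n=5, peep=5.0, noise=0.0, seed=1,
                  clean=True, **kw):
    """Constant-parameter scenario; ``clean`` disables measurement artefacts."""
    art = kw.pop("artefacts",
                 Artefacts(tail_amp=0.0, pressure_delta=0.0) if clean
                 else Artefacts())
    return SimScenario(
        peep_protocol=((peep, n),),
        elastance=Trajectory(kind="constant", value=E),
        resistance=Trajectory(kind="constant", value=R),
        artefacts=art, noise_flow=noise, noise_pressure=noise,
        seed=seed, **kw)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def clean_record():
    """Noise-free, artefact-free record: E=25, R=5, PEEP=5, 5 breaths."""
    return simulate_protocol(make_scenario())


@pytest.fixture
def noisy_record():
    """Same breaths with 5%-of-peak channel noise and default artefacts."""
    return simulate_protocol(make_scenario(n=20, noise=0.05, clean=False,
                                           seed=7))
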