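import numpy as np
import pytest
from hypothesis import settings

from antiphase import phase, stimgen

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FS = 192_000.0


@pytest.fixture(scope="session")
def masker8():
    """10 s broadband masker, 8 Hz AM, full depth (with its cycle sequence)."""
    spec = stimgen.MaskerSpec(
        carrier_band=(10, 96), sample_rate=FS, duration=10.0,
        am_schedule=8.0, modulation_depth=1.0, rng_seed=11,
    )
    return spec.render()


@pytest.fixture(scope="session")
def phase_model8(masker8):
    """Phase model recovered from the 8 Hz masker audio."""
    wav, _ = masker8
    env = phase.extract_envelope_steady(wav, 8.0)
    return phase.phase_model_from_envelope(env, [8.0])


@pytest.fixture(scope="session")
def ideal_model8(masker8):
    """Exact phase model implied by the 8 Hz cycle sequence."""
    _, cycles = masker8
    return phase.phase_model_from_cycles(cycles)


@pytest.fixture(scope="session")
def random_masker():
    """20 s random-cycle masker over the eight standard rates."""
    rates = [4, 8, 16, 25, 33, 40, 50, 80]
    wav, seq = stimgen.make_random_masker(
        rates, 20.0, FS, seed=5, block_duration=20.0
    )
    return wav, seq
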