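import pytest

from oxiloop import PhysioProfile, synthesize_stream


@pytest.fixture
def nominal_profile():
    """Healthy fingertip: SpO2 97 %, 75 bpm, PI 2 %, clean signal."""
    return PhysioProfile(true_spo2=97.0, heart_rate=75.0, perfusion_index=2.0, seed=7)


@pytest.fixture(scope="session")
def nominal_stream_20s():
    """Shared noise-free 20 s stream at the default 500 S/s."""
    profile = PhysioProfile(true_spo2=94.0, heart_rate=75.0, perfusion_index=2.0, seed=3)
    return synthesize_stream(profile, 20.0)
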