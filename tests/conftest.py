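import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import whalehht as w

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_tone_clean():
    """Noiseless 45 Hz (amp 1.0) + 12 Hz (amp 0.5), 1 s at 1000 Hz."""
    return w.make_tones(
        [w.ToneSpec(45.0, 1.0), w.ToneSpec(12.0, 0.5)], duration=1.0, rate=1000.0
    )


@pytest.fixture(scope="session")
def two_tone_decomp(two_tone_clean):
    return w.sift(two_tone_clean.samples)


@pytest.fixture(scope="session")
def random_segment_corpus():
    """Mixed synthetic segments: 1-3 tones plus noise, varied seeds and rates."""
    rng = np.random.default_rng(20260930)
    segments = []
    for i in range(30):
        rate = float(rng.choice([1000.0, 2000.0]))
        n_tones = int(rng.integers(1, 4))
        tones = [
            w.ToneSpec(
                freq=float(rng.uniform(5.0, rate / 4)),
                amplitude=float(rng.uniform(0.2, 1.0)),
                phase0=float(rng.uniform(0, 2 * np.pi)),
            )
            for _ in range(n_tones)
        ]
        rec = w.make_tones(
            tones,
            w.NoiseSpec(sd=float(rng.uniform(0.0, 0.1)), seed=int(rng.integers(2**31))),
            duration=0.5,
            rate=rate,
        )
        segments.append(rec)
    return segments
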