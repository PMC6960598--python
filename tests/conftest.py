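import numpy as np
import pytest

from ppgbp import synthgen as sg


@pytest.fixture(scope="session")
def quiet_subject():
    """Subject with no cuff-reference noise (deterministic BP function)."""
    return sg.make_subject(11, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_record(quiet_subject):
    """Noiseless 20 s record at 60 bpm: exactly 20 beats, planted truth."""
    return sg.render_record(
        quiet_subject, duration=20.0, hr=60.0, noise=None, seed=5
    )


@pytest.fixture(scope="session")
def linear_toy():
    """30-sample scalar regression toy with a known linear law y = 2x."""
    rng = np.random.default_rng(42)
    x = rng.uniform(-1.0, 3.0, 30)[:, None]
    return x, 2.0 * x.ravel()


def truth_indices(record, point):
    """Absolute sample index of a planted fiducial for every beat."""
    out = []
    for b in record.beats:
        off = 0 if point == "b" else round(getattr(b, f"t_{point}") * record.fs)
        out.append(b.onset_index + off)
    return np.array(out)
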