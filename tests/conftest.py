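import numpy as np
import pytest

from pqrst import DetectorConfig, SyntheticBeatSpec, synthesize_record

FS = 360.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def clean_record():
    """One clean default-morphology record with ground truth (30 beats)."""
    spec = SyntheticBeatSpec()
    samples, truths = synthesize_record(spec, 30, FS, seed=0)
    return samples, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def naive_bilateral(signal, params):
    """Independent double-loop reference for the adaptive bilateral filter."""
    from pqrst.bilateral import adaptive_sigmas

    x = np.asarray(signal, dtype=float)
    out = np.zeros_like(x)
    n = params.half_width
    for c in range(x.size):
        lo, hi = max(0, c - n), min(x.size, c + n + 1)
        win = x[lo:hi]
        var = float(np.mean((win - win.mean()) ** 2))
        sd, sr = adaptive_sigmas(var, params)
        num = den = 0.0
        for xi in range(lo, hi):
            w = (np.exp(-((xi - c) ** 2) / (2.0 * sd * sd))
                 * np.exp(-((x[xi] - x[c]) ** 2) / (2.0 * sr * sr)))
            num += x[xi] * w
            den += w
        out[c] = num / den
    return out
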