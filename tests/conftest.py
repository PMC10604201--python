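import numpy as np
import pytest

from ppgrr.records import PPGRecord, RRSeries
from ppgrr.synthetic import SynthConfig, generate_ppg


@pytest.fixture(scope="session")
def short_record() -> PPGRecord:
    """A 2-minute synthetic record at 125 Hz with RR fixed at 15 brpm."""
    return generate_ppg(SynthConfig(duration_s=120, fs=125, rr_brpm=15, seed=11))


@pytest.fixture(scope="session")
def eight_min_record() -> PPGRecord:
    """A full-length (8 min) synthetic record, the public-dataset shape."""
    return generate_ppg(SynthConfig(duration_s=480, fs=125, rr_brpm=17, seed=5))


@pytest.fixture
def constant_rr_record() -> PPGRecord:
    """Plain record with a constant 17-brpm RRSeries reference."""
    fs = 125.0
    n = int(480 * fs)
    rng = np.random.default_rng(0)
    t = np.arange(480, dtype=float)
    return PPGRecord(
        subject_id="const-17",
        ppg=rng.normal(size=n),
        fs=fs,
        rr_reference=RRSeries(times_s=t, rr_brpm=np.full(t.size, 17.0)),
    )
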