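import numpy as np
import pytest

from pafnet import synthetic, windows
from pafnet.containers import RRSequence


@pytest.fixture(scope="session")
def nsr_rr():
    return synthetic.generate_rr(
        synthetic.default_config("NSR", n_beats=1000, seed=11), record_id="nsr_fix")


@pytest.fixture(scope="session")
def paf_rr():
    return synthetic.generate_rr(
        synthetic.default_config("PAF_PRONE", n_beats=1000, seed=22), record_id="paf_fix")


@pytest.fixture(scope="session")
def clean_ecg():
    rr = synthetic.generate_rr(
        synthetic.default_config("NSR", n_beats=99, seed=5), record_id="ecg_fix")
    return synthetic.generate_ecg(rr, fs=250.0, noise_sd=0.0, wander_amp=0.0, seed=5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small separable window set at the minimum supported input size."""
    cfg = windows.WindowConfig(N=16, step=1)
    paf = [(synthetic.generate_rr(
        synthetic.default_config("PAF_PRONE", n_beats=215, seed=31 + i), f"p{i}"), None)
        for i in range(2)]
    nsr = [synthetic.generate_rr(
        synthetic.default_config("NSR", n_beats=215, seed=41 + i), f"n{i}")
        for i in range(2)]
    return windows.build_dataset(paf, nsr, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_rr(intervals, record_id="r") -> RRSequence:
    return RRSequence(intervals=np.asarray(intervals, dtype=float), record_id=record_id)
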