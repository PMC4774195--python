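import numpy as np
import pytest

from auxnet import OrdinalScale, simulate_y2h_dataset
from auxnet.simulate import SimulationConfig

TABLE1_LIKE = """\
# excerpt-shaped two-way Y2H table
bait\tprey\txgal\this3
BD-ARF1\tAD-ARF1\t-\t12 %
BD-ARF2\tAD-ARF1\t-\t14 %
BD-ARF1\tAD-ARF2\t-\t14 %
BD-IAA2\tAD-ARF5\t++\t90 %
BD-ARF5\tAD-IAA2\t+?\t119 %
BD-IAA3\tAD-ARF5\t++\t90 %
BD-ARF5\tAD-IAA3\t++\t121 %
BD-IAA4\tAD-ARF5\t++\t121 %
BD-ARF5\tAD-IAA4\t+++\t70 %
"""


@pytest.fixture()
def scale():
    return OrdinalScale()


@pytest.fixture()
def table1_path(tmp_path):
    p = tmp_path / "y2h.tsv"
    p.write_text(TABLE1_LIKE)
    return p


@pytest.fixture()
def clean_screen():
    """Noise-free simulated 12-protein screen with planted truth."""
    cfg = SimulationConfig(n=12, Q=2, pi=(0.8, 0.15), seed=11)
    roster, records, truth = simulate_y2h_dataset(cfg)
    return cfg, roster, records, truth


def random_symmetric(rng, n, low=0.0, high=1.0):
    A = rng.uniform(low, high, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A
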