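import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sweepabc.haplotypes import HaplotypeSample

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_sample(matrix, positions=None, pops=None, focal=None, length=None):
    matrix = np.asarray(matrix, dtype=np.uint8)
    n, s = matrix.shape
    if positions is None:
        positions = np.arange(s, dtype=float) * 100.0
    if pops is None:
        pops = ["A"] * n
    return HaplotypeSample(
        matrix=matrix, positions=np.asarray(positions, float),
        pop_labels=np.array(pops), focal_index=focal, region_length=length)


@pytest.fixture
def toy_sample():
    """The 4-haplotype {00, 01, 11, 11} sample used across the SFS tests."""
    return make_sample([[0, 0], [0, 1], [1, 1], [1, 1]])


@pytest.fixture
def two_pop_sample():
    """Small two-population sample with a focal site."""
    rng = np.random.default_rng(42)
    n = 40
    s = 12
    m = (rng.random((n, s)) < 0.35).astype(np.uint8)
    m[:20, 5] = (rng.random(20) < 0.3).astype(np.uint8)
    m[20:, 5] = (rng.random(20) < 0.9).astype(np.uint8)
    if m[:, 5].min() == m[:, 5].max():
        m[0, 5] = 1 - m[0, 5]
    return make_sample(m, positions=np.linspace(0, 1100, s),
                       pops=["A"] * 20 + ["B"] * 20, focal=5, length=1200)
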