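import numpy as np
import pytest

from combotx.synthetic import HillModelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def hill_m2():
    """Noise-free Hill curve with slope 2 and median-effect dose 50."""
    return HillModelSpec(slope_m=2.0, median_dose_dm=50.0)


def brute_force_es(genes, scores, members, weight_p=1.0):
    """Step-by-step running-sum oracle, independent of the package code."""
    members = set(members)
    n = len(genes)
    n_hits = sum(1 for g in genes if g in members)
    total_w = sum(abs(s) ** weight_p for g, s in zip(genes, scores) if g in members)
    running = 0.0
    best = 0.0
    for g, s in zip(genes, scores):
        if g in members:
            running += (abs(s) ** weight_p) / total_w if total_w > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best
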