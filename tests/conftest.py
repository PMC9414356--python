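import numpy as np
import pytest

from amorphkin import synthetic as syn


def avrami_time_grid(stages, n_points=200, x_lo=0.01, x_hi=0.99):
    """Log-spaced time grid covering X in [x_lo, x_hi] for all stages.

    ``stages`` is an iterable of (k, n) pairs; the grid spans the earliest
    x_lo crossing to the latest x_hi crossing among them.
    """
    los, his = [], []
    for k, n in stages:
        los.append((-np.log1p(-x_lo) / k) ** (1.0 / n))
        his.append((-np.log1p(-x_hi) / k) ** (1.0 / n))
    return np.geomspace(min(los), max(his), n_points)


@pytest.fixture
def neat_drug_truth():
    """Synthetic heating-run truth for the neat drug: Tg 273 K, peak 317.3 K."""
    return syn.DscTruth(Tg_mid=273.0, Tp=317.3, peak_width=3.0, enthalpy=50.0)


@pytest.fixture
def fine_grid():
    return np.arange(250.0, 345.0, 0.05)
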