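import numpy as np
import pytest

from ntcpkit import DVH


@pytest.fixture
def step_dvh():
    """Cumulative step: whole 100 cc organ at exactly 1 Gy."""
    return DVH("organ", "cumulative", [0, 1, 2], [100, 100, 0])


@pytest.fixture
def ramp_dvh():
    """Cumulative [100, 60, 25, 0] cc at [0, 20, 40, 60] Gy."""
    return DVH("organ", "cumulative", [0, 20, 40, 60], [100, 60, 25, 0])


def random_cumulative_dvh(rng: np.random.Generator, n_bins: int = 40,
                          structure: str = "organ") -> DVH:
    """A random valid cumulative DVH on a uniform grid."""
    total = rng.uniform(10, 500)
    drops = rng.dirichlet(np.ones(n_bins)) * total
    vol = total - np.concatenate(([0.0], np.cumsum(drops)))[:-1]
    vol = np.concatenate((vol, [max(vol[-1] - drops[-1], 0.0)]))
    dose = np.linspace(0, rng.uniform(20, 70), n_bins + 1)
    return DVH(structure, "cumulative", dose, np.maximum(vol, 0.0))
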