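import numpy as np
import pytest

from knotmetrics import make_tabulated_knot
from knotmetrics.dynamics import SimulationParams, sample_ensemble
from knotmetrics.forcefield import ForceField


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def trefoil_ensemble():
    """Short thermal ensemble of a 63-bead trefoil (shared by several
    tests to amortize the simulation cost)."""
    params = SimulationParams(n_equil_steps=60_000, n_prod_steps=120_000,
                              sample_stride=1_000, seed=11)
    return sample_ensemble(make_tabulated_knot("3_1", 63),
                           ForceField(k_bend=1.0), params)


@pytest.fixture(scope="session")
def random_coil_fixtures(rng):
    """Self-avoiding-ish random bead chains used as electrostatics
    cross-validation fixtures (closed rings of modest wiggliness)."""
    from knotmetrics.geometry import make_circle, RingConfiguration
    out = []
    for n in (10, 24, 63, 126):
        base = make_circle(n).positions
        for k in range(3):
            pts = base + 0.25 * rng.standard_normal(base.shape)
            out.append(RingConfiguration(pts, closed=True, knot_label="0_1"))
    return out
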