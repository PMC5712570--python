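import numpy as np
import pytest

from spool import SPConfig, SpatialPooler


@pytest.fixture
def flat_sp():
    """Small dimensionless pooler: 64 columns over 64 inputs, global k-WTA."""
    cfg = SPConfig.dimensionless(n_columns=64, input_dims=(64,), seed=7)
    return SpatialPooler(cfg)


@pytest.fixture
def grid_sp():
    """Small topological pooler: 12x12 columns over 12x12 inputs, radius 2."""
    cfg = SPConfig.topological(input_dims=(12, 12), column_dims=(12, 12),
                               potential_radius=2, seed=7)
    return SpatialPooler(cfg)


def make_single_column_sp(weights, boost=1.0):
    """One column over len(weights) inputs with a hand-set connected row."""
    w = np.asarray(weights, dtype=float)
    cfg = SPConfig.dimensionless(n_columns=1, input_dims=(w.size,), seed=0)
    sp = SpatialPooler(cfg)
    sp.permanences[0] = np.where(w > 0, 1.0, 0.0)
    sp.connected = (sp.permanences >= cfg.connection_threshold) & sp.potential
    sp._Wf = sp.connected.astype(np.float64)
    sp.boosts[0] = boost
    return sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
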