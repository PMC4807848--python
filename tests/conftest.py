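"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from blipsim import blip_packing as bp
from blipsim import discrete_fold_model as dfm


@pytest.fixture(scope="session")
def unit_circle_1000():
    th = np.linspace(0.0, 2.0 * np.pi, 1000, endpoint=False)
    return np.column_stack([np.cos(th), np.sin(th)])


@pytest.fixture(scope="session")
def packed_cell_300():
    """One seed-and-growth packing reused by several tests."""
    pts = bp.sample_uniform_sphere(300, 1.0, seed=0)
    return pts, bp.grow_blips(pts, 1.0)


@pytest.fixture(scope="session")
def steady_states():
    """Steady folded states for the acceptance grid, computed once.

    Keys are (M, ER); values are (MinimizeResult, ModelParams).
    """
    out = {}
    for M, ER in [(20, 4.0), (40, 4.0), (50, 4.0), (40, 2.0), (40, 6.0)]:
        params = dfm.ModelParams(N=400, M=M, ER=ER)
        out[(M, ER)] = (dfm.steady_state(params), params)
    return out
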