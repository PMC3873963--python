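import numpy as np
import pytest

from secrpp import (
    AreaCaptures,
    AreaDesign,
    AreaParams,
    DetectionParams,
    IntensityParams,
    Region,
    TrapCaptures,
    TrapDesign,
    build_grid,
)


@pytest.fixture
def unit_ss():
    """3x3 pixel grid over the unit square."""
    return build_grid(Region(0.0, 1.0, 0.0, 1.0), 1.0 / 3.0)


@pytest.fixture
def tiny_trap_instance():
    """Minimal trap-array instance: 2x1 pixel grid, 1 trap, J=1, n=1."""
    ss = build_grid(Region(0.0, 1.0, 0.0, 0.5), 0.5)
    design = TrapDesign(np.array([[0.3, 0.25]]), J=1)
    det = DetectionParams(0.4, 0.3)
    ip = IntensityParams([np.log(5.0)])
    data = TrapCaptures(np.array([[1]]))
    return ss, design, det, ip, data


@pytest.fixture
def small_area_instance():
    """Small area-search instance: 4x4 pixels, J=2, n=2."""
    ss = build_grid(Region(0.0, 1.0, 0.0, 1.0), 0.25)
    S = Region(0.25, 0.75, 0.25, 0.75)
    design = AreaDesign(S, J=2)
    ap = AreaParams(0.6, 0.2)
    ip = IntensityParams([np.log(12.0)])
    w = np.array([[1, 0], [1, 1]])
    u = np.full((2, 2, 2), np.nan)
    u[0, 0] = (0.4, 0.5)
    u[1, 0] = (0.6, 0.3)
    u[1, 1] = (0.55, 0.45)
    data = AreaCaptures(w, u)
    return ss, design, ap, ip, data
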