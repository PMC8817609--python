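import numpy as np
import pytest

from ctifr.boundary_conditions import BoundaryConditions
from ctifr.vessel_geometry import CenterlineTree, Segment, TreeParams


def straight_tube(length=30.0, radius=1.5, n_points=61, label="tube"):
    """Single-segment straight tube along x, uniform radius (mm)."""
    x = np.linspace(0.0, length, n_points)
    pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    seg = Segment(0, pts, np.full(n_points, float(radius)))
    return CenterlineTree({0: seg}, inlet=0, outlets=[0], label=label)


def y_tree(parent_radius=2.0, child_radii=(1.5, 1.5), parent_len=20.0,
           child_len=20.0, n=41):
    """Symmetric-topology bifurcation: one parent, two straight children."""
    x = np.linspace(0.0, parent_len, n)
    p = Segment(0, np.column_stack([x, np.zeros(n), np.zeros(n)]),
                np.full(n, parent_radius), children=[1, 2])
    tip = p.points[-1]
    t = np.linspace(0.0, child_len, n)
    d1 = np.array([np.cos(0.4), np.sin(0.4), 0.0])
    d2 = np.array([np.cos(-0.4), np.sin(-0.4), 0.0])
    c1 = Segment(1, tip + t[:, None] * d1, np.full(n, child_radii[0]), parent=0)
    c2 = Segment(2, tip + t[:, None] * d2, np.full(n, child_radii[1]), parent=0)
    return CenterlineTree({0: p, 1: c1, 2: c2}, inlet=0, outlets=[1, 2])


@pytest.fixture
def tube():
    return straight_tube()

@pytest.fixture
def bifurcation():
    return y_tree()


@pytest.fixture
def fixed_flow_bc():
    """BC delivering exactly 90 mL/min (= 1.5e-6 m^3/s) at 80 mmHg.

    Uses a unit mass with a linear flow law so the inlet flow is the
    coefficient itself.
    """
    return BoundaryConditions(Pa_diastolic=80.0, LV_mass=1.0,
                              flow_coefficient=90.0, flow_exponent=1.0)


@pytest.fixture
def standard_tree_params():
    """The standard synthetic test vessel: mid-LAD lesion, DS 50."""
    return TreeParams(stenoses=((45.0, 10.0, 50.0),))
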