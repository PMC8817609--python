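"""Boundary conditions for the centerline flow model.

The scheme mirrors how CT-derived resting indices are computed in practice:

* inlet flow from left-ventricular myocardial mass through an allometric
  relation ``Q = c * M**alpha`` (resting flow; a hyperemic mode scales it by
  a factor ``h`` for the FFR surrogate),
* outlet flows split between terminal branches by Murray's law,
  ``Q_i ∝ d_i**gamma`` with the classical exponent gamma = 3,
* inlet pressure equal to the diastolic aortic root pressure, the natural
  reference for a wave-free-period (diastolic) index.

Flows are handled in mL/min at this interface and converted to SI by the
solver; pressures leave this module already in SI (Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .vessel_geometry import CenterlineTree, _require_valid

MMHG_TO_PA = 133.322
ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0

#: length of the distal window used to measure an outlet's diameter (mm)
OUTLET_WINDOW_MM = 3.0


@dataclass(frozen=True)
class BoundaryConditions:
    """Patient parameters, physical constants and model coefficients.

    Parameters
    ----------
    Pa_diastolic:
        Diastolic aortic root pressure (mmHg); the inlet pressure and the
        denominator of the pressure-ratio index.
    LV_mass:
        Myocardial mass perfused by the tree (g).
    flow_coefficient, flow_exponent:
        Allometric resting-flow law ``Q[mL/min] = c * M[g]**alpha``.
        Defaults c = 3.41, alpha = 0.75 give ~246 mL/min for a 300 g heart,
        a plausible total resting coronary flow.
    murray_exponent:
        Diameter exponent of the outlet split (classical value 3).
    hyperemic_factor:
        Flow multiplier applied in hyperemic mode only (adenosine-like
        hyperemia raises coronary flow ~3-4x); used for the FFR surrogate.
    blood_density, blood_viscosity:
        Newtonian blood model: 1056 kg/m^3 and 0.0035 Pa.s.
    """

    Pa_diastolic: float = 80.0
    LV_mass: float = 120.0
    flow_coefficient: float = 3.41
    flow_exponent: float = 0.75
    murray_exponent: float = 3.0
    hyperemic_factor: float = 3.0
    blood_density: float = 1056.0
    blood_viscosity: float = 0.0035

    def __post_init__(self) -> None:
        checks = {
            "Pa_diastolic": self.Pa_diastolic > 0,
            "LV_mass": self.LV_mass > 0,
            "flow_coefficient": self.flow_coefficient > 0,
            "murray_exponent": self.murray_exponent > 0,
            "hyperemic_factor": self.hyperemic_factor >= 1.0,
            "blood_density": self.blood_density > 0,
            "blood_viscosity": self.blood_viscosity > 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise InvalidParameterError(f"invalid boundary parameters: {bad}")


@dataclass
class TreeBoundaryData:
    """Resolved boundary data for one solve on one tree."""

    segment_flows_ml_min: dict[int, float]
    outlet_flows_ml_min: dict[int, float]
    inlet_flow_ml_min: float
    inlet_pressure_pa: float
    mode: str
    bc: BoundaryConditions = field(repr=False, default=None)


def inlet_flow_from_mass(LV_mass: float, c: float = 3.41, alpha: float = 0.75
                         ) -> float:
    """Resting inlet flow (mL/min) from myocardial mass (g): ``c * M**alpha``."""
    if not LV_mass > 0:
        raise InvalidParameterError(f"LV mass must be > 0 g, got {LV_mass}")
    return c * LV_mass ** alpha


def murray_outlet_split(total_flow: float, diameters, gamma: float = 3.0
                        ) -> np.ndarray:
    """Split ``total_flow`` across outlets as ``Q_i = Q * d_i**g / sum d_j**g``.

    The last outlet absorbs the floating-point residual so the flows sum to
    ``total_flow`` exactly.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise InvalidParameterError("at least one outlet is required")
    if np.any(d <= 0):
        raise InvalidParameterError("outlet diameters must all be > 0")
    w = d ** gamma
    q = total_flow * w / w.sum()
    q[-1] = total_flow - q[:-1].sum()
    return q


def outlet_diameter(tree: CenterlineTree, outlet_id: int,
                    window: float = OUTLET_WINDOW_MM) -> float:
    """Outlet lumen diameter: 2x the mean radius over the distal ``window`` mm.

    Averaging over a short distal window damps discretization noise in the
    terminal samples.
    """
    seg = tree.segments[outlet_id]
    s = seg.arclengths
    mask = s >= s[-1] - window
    return 2.0 * float(np.mean(seg.radii[mask]))


def assemble_bc(tree: CenterlineTree, bc: BoundaryConditions,
                mode: str = "resting") -> TreeBoundaryData:
    """Resolve per-segment flows and inlet pressure for one solve.

    Flow is conserved exactly at every junction: leaf flows come from the
    Murray split and each internal segment's flow is the sum of its
    children's, so parent minus sum-of-children is identically zero.
    """
    if mode not in ("resting", "hyperemic"):
        raise InvalidParameterError(f"mode must be resting|hyperemic, got {mode!r}")
    _require_valid(tree)
    q_in = inlet_flow_from_mass(bc.LV_mass, bc.flow_coefficient, bc.flow_exponent)
    if mode == "hyperemic":
        q_in *= bc.hyperemic_factor
    outlets = list(tree.outlets)
    diam = [outlet_diameter(tree, o) for o in outlets]
    q_out = murray_outlet_split(q_in, diam, bc.murray_exponent)
    outlet_flows = dict(zip(outlets, (float(q) for q in q_out)))

    seg_flows: dict[int, float] = {}

    def _fill(sid: int) -> float:
        seg = tree.segments[sid]
        q = outlet_flows[sid] if not seg.children else \
            sum(_fill(c) for c in seg.children)
        seg_flows[sid] = q
        return q

    _fill(tree.inlet)
    return TreeBoundaryData(
        segment_flows_ml_min=seg_flows,
        outlet_flows_ml_min=outlet_flows,
        inlet_flow_ml_min=float(q_in),
        inlet_pressure_pa=bc.Pa_diastolic * MMHG_TO_PA,
        mode=mode,
        bc=bc,
    )
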