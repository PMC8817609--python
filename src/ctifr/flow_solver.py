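"""Reduced-order steady pressure solver and the wave-free pressure-ratio index.

The tree is treated as a network of 1D segments carrying a prescribed
steady flow.  Marching from the inlet, pressure drops accumulate from two
loss terms per discretization step:

* a viscous (Poiseuille) term ``8*pi*mu*Q*ds / A_bar**2`` with
  ``A_bar = (A_in + A_out) / 2`` — exact for a uniform tube;
* a Borda-Carnot expansion (pressure-recovery) loss downstream of a
  stenosis throat, ``K_e * (rho/2) * Q**2 * (1/A_throat - 1/A)**2``,
  accumulated over each monotone-expanding run so the total is independent
  of the discretization step.

Children inherit their parent's terminal pressure (pressure continuity at
junctions).  The index is the pressure ratio R = P / P_inlet evaluated at a
measurement point 30 mm downstream of the lesion throat — the conventional
distal-sensor position — clamped to the vessel end.  R <= 0.89 marks a
hemodynamically significant lesion (the wave-free-ratio cutoff); a
hyperemic solve evaluated the same way is the FFR surrogate with its 0.80
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary_conditions import ML_PER_MIN_TO_M3_PER_S, TreeBoundaryData
from .errors import DegeneratePhysicsError, InvalidParameterError
from .vessel_geometry import CenterlineTree

#: cutoff for the resting (wave-free) index
IFR_CUTOFF = 0.89
#: cutoff for the hyperemic (FFR-surrogate) index
FFR_CUTOFF = 0.80
#: default sensor position downstream of the lesion throat (mm)
MEASUREMENT_OFFSET_MM = 30.0
#: default expansion-loss coefficient
DEFAULT_K_EXPANSION = 1.0

MM_TO_M = 1e-3


def step_pressure_drop(Q: float, A_in: float, A_out: float, ds: float,
                       mu: float, rho: float,
                       k_expansion: float = DEFAULT_K_EXPANSION,
                       A_throat: float | None = None) -> float:
    """Pressure drop (Pa) over one centerline step, SI units throughout.

    ``dP = dP_visc + dP_exp`` with ``dP_visc = 8*pi*mu*Q*ds / A_bar**2``
    (``A_bar`` the mean of the endpoint areas) and, when the step expands
    (``A_out > A_in``), a Borda-Carnot recovery loss referenced to the
    upstream throat area (defaults to ``A_in``, i.e. the single-step form
    ``K_e*(rho/2)*Q**2*(1/A_in - 1/A_out)**2``).  Passing the running
    throat area telescopes consecutive expanding steps so a smooth recovery
    converges with grid refinement.
    """
    if Q < 0:
        raise InvalidParameterError("flow reversal unsupported (Q < 0)")
    if A_in <= 0 or A_out <= 0 or ds <= 0:
        raise InvalidParameterError("areas and step length must be > 0")
    a_bar = 0.5 * (A_in + A_out)
    dp = 8.0 * np.pi * mu * Q * ds / a_bar ** 2
    if A_out > A_in:
        at = A_in if A_throat is None else A_throat
        new = (1.0 / at - 1.0 / A_out)
        old = max(0.0, 1.0 / at - 1.0 / A_in)
        dp += k_expansion * 0.5 * rho * Q * Q * (new * new - old * old)
    return dp


@dataclass
class FlowSolution:
    """Pressure/ratio fields over one tree for one boundary mode."""

    pressures: dict[int, np.ndarray]      # Pa, aligned with segment points
    ratios: dict[int, np.ndarray]         # P / P_inlet
    segment_flows: dict[int, float]       # m^3/s
    inlet_pressure: float                 # Pa
    mode: str
    settings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VesselResult:
    """Index value(s) at the measurement point of one vessel."""

    accuifrct: float
    significant: bool
    ds_percent: float
    measurement_arclength: float  # mm from the inlet along the sensor path
    ffr_surrogate: float | None = None
    ffr_significant: bool | None = None


def solve_pressure_field(tree: CenterlineTree, bc_data: TreeBoundaryData,
                         k_expansion: float = DEFAULT_K_EXPANSION
                         ) -> FlowSolution:
    """March the pressure field downstream from the inlet.

    Expects a validated, resampled tree and conservative per-segment flows
    (the output of ``assemble_bc``).  Deterministic; raises
    :class:`DegeneratePhysicsError` if any pressure falls to or below zero,
    which signals flow the geometry cannot physically carry at this inlet
    pressure.
    """
    mu = bc_data.bc.blood_viscosity
    rho = bc_data.bc.blood_density
    p_inlet = bc_data.inlet_pressure_pa

    pressures: dict[int, np.ndarray] = {}
    ratios: dict[int, np.ndarray] = {}
    flows_si = {sid: q * ML_PER_MIN_TO_M3_PER_S
                for sid, q in bc_data.segment_flows_ml_min.items()}

    order: list[int] = [tree.inlet]
    order += tree.descendants(tree.inlet)
    entry_pressure = {tree.inlet: p_inlet}

    for sid in order:
        seg = tree.segments[sid]
        q = flows_si[sid]
        r_m = seg.radii * MM_TO_M
        area = np.pi * r_m ** 2
        ds = np.diff(seg.arclengths) * MM_TO_M
        p = np.empty(seg.n_points)
        p[0] = entry_pressure[sid]
        a_throat = area[0]
        for i in range(ds.size):
            a_in, a_out = area[i], area[i + 1]
            if a_out <= a_in:
                a_throat = min(a_throat, a_out)  # contracting: track the throat
                drop = step_pressure_drop(q, a_in, a_out, ds[i], mu, rho,
                                          k_expansion)
            else:
                drop = step_pressure_drop(q, a_in, a_out, ds[i], mu, rho,
                                          k_expansion, A_throat=a_throat)
                if a_out >= area[0]:
                    a_throat = a_out  # lumen fully recovered; reset episode
            p[i + 1] = p[i] - drop
            if p[i + 1] <= 0.0:
                raise DegeneratePhysicsError(
                    f"pressure fell to {p[i + 1]:.1f} Pa at segment {sid}, "
                    f"point {i + 1}: flow {q:.3g} m^3/s exceeds what this "
                    "geometry can carry at the given inlet pressure",
                    segment_id=sid, point_index=i + 1)
        pressures[sid] = p
        ratios[sid] = p / p_inlet
        for c in seg.children:
            entry_pressure[c] = p[-1]

    return FlowSolution(
        pressures=pressures, ratios=ratios, segment_flows=flows_si,
        inlet_pressure=p_inlet, mode=bc_data.mode,
        settings={"k_expansion": k_expansion},
    )


def _lesion_point(tree: CenterlineTree) -> tuple[int, float] | None:
    """Locate the lesion throat: global minimal-radius point, if focal.

    The candidate segment is the one with the largest DS% against its own
    proximal reference; a tree whose worst segment shows DS < 10% (bare
    taper) is treated as lesion-free.
    """
    from .vessel_geometry import segment_ds

    best: tuple[float, int] | None = None
    for sid, seg in tree.segments.items():
        ds = segment_ds(seg)
        if best is None or ds > best[0]:
            best = (ds, sid)
    if best is None or best[0] < 10.0:
        return None
    seg = tree.segments[best[1]]
    i = int(np.argmin(seg.radii))
    return best[1], float(seg.arclengths[i])


def index_at_measurement_point(solution: FlowSolution, tree: CenterlineTree,
                               lesion: tuple[int, float] | None = None,
                               hyperemic_solution: FlowSolution | None = None,
                               offset: float = MEASUREMENT_OFFSET_MM
                               ) -> VesselResult:
    """Evaluate the index 30 mm downstream of the lesion throat.

    ``lesion`` is a (segment id, local arclength mm) pair; when omitted the
    throat is auto-detected as the tree's minimal-radius point (an error if
    no focal lesion exists).  Walking downstream follows the main
    continuation (largest-flow child) and clamps at the vessel's distal
    end.  When a hyperemic solution is supplied, the FFR surrogate is read
    at the same point.
    """
    from .vessel_geometry import segment_ds

    if lesion is None:
        lesion = _lesion_point(tree)
        if lesion is None:
            raise InvalidParameterError(
                "no focal lesion found and no measurement point given")
    sid, s_local = lesion
    if sid not in tree.segments:
        raise InvalidParameterError(f"lesion segment {sid} not in tree")

    prefix = 0.0
    anc = tree.segments[sid].parent
    while anc is not None:
        prefix += tree.segments[anc].length
        anc = tree.segments[anc].parent

    remaining = offset
    cur = sid
    s_target = s_local
    path_arclength = prefix + s_local
    while True:
        seg = tree.segments[cur]
        room = seg.length - s_target
        if remaining <= room or not seg.children:
            s_target = min(seg.length, s_target + remaining)
            path_arclength += min(remaining, room)
            break
        remaining -= room
        path_arclength += room
        cur = max(seg.children,
                  key=lambda c: solution.segment_flows.get(c, 0.0))
        s_target = 0.0

    seg = tree.segments[cur]
    i = int(np.argmin(np.abs(seg.arclengths - s_target)))
    value = float(solution.ratios[cur][i])
    ds_pct = max(segment_ds(tree.segments[s]) for s in tree.segments)

    ffr = ffr_sig = None
    if hyperemic_solution is not None:
        ffr = float(hyperemic_solution.ratios[cur][i])
        ffr_sig = ffr <= FFR_CUTOFF
    return VesselResult(
        accuifrct=value,
        significant=value <= IFR_CUTOFF,
        ds_percent=float(ds_pct),
        measurement_arclength=float(path_arclength),
        ffr_surrogate=ffr,
        ffr_significant=ffr_sig,
    )
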