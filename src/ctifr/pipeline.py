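"""High-level convenience wrapper: tree + patient parameters -> index."""

from __future__ import annotations

from .boundary_conditions import BoundaryConditions, assemble_bc
from .flow_solver import (DEFAULT_K_EXPANSION, FlowSolution, VesselResult,
                          index_at_measurement_point, solve_pressure_field)
from .vessel_geometry import CenterlineTree, DEFAULT_STEP_MM, resample_centerline


def compute_index(tree: CenterlineTree, bc: BoundaryConditions,
                  lesion: tuple[int, float] | None = None,
                  step: float = DEFAULT_STEP_MM,
                  k_expansion: float = DEFAULT_K_EXPANSION,
                  with_hyperemic: bool = True,
                  measurement_offset: float | None = None,
                  ) -> tuple[VesselResult, FlowSolution]:
    """Resample, assemble boundary conditions, solve, and read the index.

    Returns the vessel result (resting index, optional FFR surrogate and
    the 0.89 / 0.80 significance calls) together with the resting solution
    field.  ``lesion`` is an optional (segment id, local arclength mm)
    measurement anchor; by default the lesion throat is auto-detected.
    """
    rtree = resample_centerline(tree, step)
    rest = solve_pressure_field(rtree, assemble_bc(rtree, bc, "resting"),
                                k_expansion)
    hyper = None
    if with_hyperemic:
        hyper = solve_pressure_field(rtree, assemble_bc(rtree, bc, "hyperemic"),
                                     k_expansion)
    kwargs = {} if measurement_offset is None else {"offset": measurement_offset}
    result = index_at_measurement_point(rest, rtree, lesion=lesion,
                                        hyperemic_solution=hyper, **kwargs)
    return result, rest
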