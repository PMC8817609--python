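"""Centerline-based coronary tree geometry.

A coronary tree is modelled as a set of :class:`Segment` polylines (3D
centerline points with lumen radii, in mm) connected into a rooted,
diverging tree: one inlet, every leaf an outlet.  This module defines the
containers, validation, resampling, parametric stenosis insertion, anatomic
severity (percent diameter stenosis, DS%), a seeded synthetic-tree
generator, and serialization to the ``ctifr-tree/1`` JSON schema plus an
optional legacy-ASCII VTK polydata export for visualization.

Units are clinical at this layer: millimetres everywhere.  Conversion to SI
happens inside the flow solver only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, SchemaError

TREE_SCHEMA = "ctifr-tree/1"

#: tolerance (mm) for parent-end / child-start coincidence
JUNCTION_TOL_MM = 1e-6

#: default uniform resampling step (mm); ~ CT voxel scale
DEFAULT_STEP_MM = 0.5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CenterlinePoint:
    """One centerline sample: position (mm), lumen radius (mm), arclength (mm)."""

    position: tuple[float, float, float]
    radius: float
    arclength: float


@dataclass
class Segment:
    """An unbranched run of centerline points.

    ``points`` is an (N, 3) array of positions in mm, ``radii`` the matching
    (N,) lumen radii in mm.  ``parent`` is the parent segment id or ``None``
    for the root; ``children`` the ids of daughter segments.
    """

    id: int
    points: np.ndarray
    radii: np.ndarray
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arclength from the segment start (mm)."""
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def point(self, i: int) -> CenterlinePoint:
        return CenterlinePoint(tuple(self.points[i]), float(self.radii[i]),
                               float(self.arclengths[i]))

    def copy(self) -> "Segment":
        return Segment(self.id, self.points.copy(), self.radii.copy(),
                       self.parent, list(self.children))


@dataclass
class CenterlineTree:
    """A rooted, diverging coronary centerline tree."""

    segments: dict[int, Segment]
    inlet: int
    outlets: list[int]
    label: str = "synthetic"

    def segment(self, sid: int) -> Segment:
        return self.segments[sid]

    def copy(self) -> "CenterlineTree":
        return CenterlineTree({k: s.copy() for k, s in self.segments.items()},
                              self.inlet, list(self.outlets), self.label)

    # -- traversal helpers ---------------------------------------------------

    def descendants(self, sid: int) -> list[int]:
        """All segment ids strictly below ``sid`` (depth-first, deterministic)."""
        out: list[int] = []
        stack = list(reversed(self.segments[sid].children))
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(reversed(self.segments[s].children))
        return out

    def leaves_below(self, sid: int) -> list[int]:
        """Outlet segment ids in the subtree rooted at ``sid`` (inclusive)."""
        subtree = [sid] + self.descendants(sid)
        return [s for s in subtree if not self.segments[s].children]


@dataclass(frozen=True)
class StenosisSpec:
    """A parametric focal lesion on one segment.

    ``center`` and ``length`` are arclengths in mm measured along the
    segment; ``severity`` is diameter stenosis DS in percent (0 <= DS < 100)
    relative to the local (pre-lesion) radius.  The default ``cosine``
    profile multiplies the radius by ``1 - (DS/100) * w(u)`` with
    ``w(u) = (1 + cos(2*pi*u)) / 2`` for normalized offset u in [-1/2, 1/2],
    i.e. full severity at the center and untouched shoulders.
    """

    segment_id: int
    center: float
    length: float
    severity: float
    profile: str = "cosine"


@dataclass(frozen=True)
class Violation:
    """One invariant breach found by :func:`validate_tree`."""

    segment_id: int | None
    reason: str

    def __str__(self) -> str:  # pragma: no cover - convenience only
        where = "tree" if self.segment_id is None else f"segment {self.segment_id}"
        return f"{where}: {self.reason}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_tree(tree: CenterlineTree) -> list[Violation]:
    """Check every CenterlineTree invariant; return all violations found.

    An empty list means the tree is valid.  Violations are reported, never
    raised, so callers can collect a full diagnosis of a bad input.
    """
    v: list[Violation] = []

    if tree.inlet not in tree.segments:
        v.append(Violation(None, f"inlet segment {tree.inlet} does not exist"))
        return v

    for sid, seg in tree.segments.items():
        if seg.id != sid:
            v.append(Violation(sid, f"segment id field {seg.id} != key {sid}"))
        if seg.n_points < 2:
            v.append(Violation(sid, f"segment has {seg.n_points} point(s); >= 2 required"))
            continue
        bad = np.flatnonzero(seg.radii <= 0)
        for i in bad:
            v.append(Violation(sid, f"non-positive radius {seg.radii[i]:g} mm at point {i}"))
        steps = np.linalg.norm(np.diff(seg.points, axis=0), axis=1)
        if np.any(steps <= 0):
            i = int(np.flatnonzero(steps <= 0)[0])
            v.append(Violation(sid, f"arclength not strictly increasing at point {i + 1}"))

    # topology: single root, parent/child symmetry, connectivity, acyclicity
    roots = [sid for sid, s in tree.segments.items() if s.parent is None]
    if len(roots) != 1:
        v.append(Violation(None, f"expected exactly one root, found {sorted(roots)}"))
    elif roots[0] != tree.inlet:
        v.append(Violation(None, f"root is {roots[0]} but inlet declared as {tree.inlet}"))

    for sid, seg in tree.segments.items():
        if seg.parent is not None:
            if seg.parent not in tree.segments:
                v.append(Violation(sid, f"parent {seg.parent} does not exist"))
                continue
            par = tree.segments[seg.parent]
            if sid not in par.children:
                v.append(Violation(sid, f"not listed among children of parent {seg.parent}"))
            if seg.n_points and par.n_points:
                gap = float(np.linalg.norm(seg.points[0] - par.points[-1]))
                if gap > JUNCTION_TOL_MM:
                    v.append(Violation(
                        sid, f"start is {gap:.6g} mm from end of parent {seg.parent}"))
        for c in seg.children:
            if c not in tree.segments:
                v.append(Violation(sid, f"child {c} does not exist"))
            elif tree.segments[c].parent != sid:
                v.append(Violation(sid, f"child {c} does not point back to this segment"))

    # reachability / acyclicity from the inlet
    seen: set[int] = set()
    stack = [tree.inlet]
    while stack:
        s = stack.pop()
        if s in seen:
            v.append(Violation(s, "cycle detected"))
            continue
        seen.add(s)
        stack.extend(c for c in tree.segments[s].children if c in tree.segments)
    unreachable = set(tree.segments) - seen
    for s in sorted(unreachable):
        v.append(Violation(s, "unreachable from inlet"))

    leaves = sorted(sid for sid, s in tree.segments.items() if not s.children)
    if sorted(tree.outlets) != leaves:
        v.append(Violation(None,
                           f"outlets {sorted(tree.outlets)} != leaf segments {leaves}"))
    return v


def _require_valid(tree: CenterlineTree) -> None:
    bad = validate_tree(tree)
    if bad:
        raise InvalidParameterError(
            "invalid tree: " + "; ".join(str(b) for b in bad))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_centerline(tree: CenterlineTree, step: float = DEFAULT_STEP_MM
                        ) -> CenterlineTree:
    """Re-discretize every segment at uniform arclength spacing <= ``step``.

    Positions and radii are linearly interpolated in arclength; segment
    endpoints are preserved exactly, topology is untouched.  Idempotent when
    the tree is already uniform at the requested step.
    """
    if not (step > 0):
        raise InvalidParameterError(f"resampling step must be > 0, got {step}")
    _require_valid(tree)
    new = {}
    for sid, seg in tree.segments.items():
        s = seg.arclengths
        total = s[-1]
        n_int = max(1, int(math.ceil(total / step - 1e-12)))
        s_new = np.linspace(0.0, total, n_int + 1)
        pts = np.column_stack([np.interp(s_new, s, seg.points[:, k]) for k in range(3)])
        # pin endpoints to avoid interpolation round-off
        pts[0], pts[-1] = seg.points[0], seg.points[-1]
        radii = np.interp(s_new, s, seg.radii)
        radii[0], radii[-1] = seg.radii[0], seg.radii[-1]
        new[sid] = Segment(sid, pts, radii, seg.parent, list(seg.children))
    return CenterlineTree(new, tree.inlet, list(tree.outlets), tree.label)


# ---------------------------------------------------------------------------
# stenosis insertion and severity
# ---------------------------------------------------------------------------

def stenosis_multiplier(u: np.ndarray, severity: float, profile: str = "cosine"
                        ) -> np.ndarray:
    """Radius multiplier ``1 - (DS/100) * w(u)`` for normalized offsets u."""
    if profile != "cosine":
        raise InvalidParameterError(f"unknown stenosis profile {profile!r}")
    w = np.where(np.abs(u) <= 0.5, (1.0 + np.cos(2.0 * np.pi * u)) / 2.0, 0.0)
    return 1.0 - (severity / 100.0) * w


def insert_stenosis(tree: CenterlineTree, spec: StenosisSpec) -> CenterlineTree:
    """Return a copy of ``tree`` with the focal lesion of ``spec`` applied."""
    if not (0.0 <= spec.severity < 100.0):
        raise InvalidParameterError(f"severity must be in [0, 100), got {spec.severity}")
    if not (spec.length > 0):
        raise InvalidParameterError(f"lesion length must be > 0, got {spec.length}")
    if spec.segment_id not in tree.segments:
        raise InvalidParameterError(f"segment {spec.segment_id} not in tree")
    out = tree.copy()
    seg = out.segments[spec.segment_id]
    lo, hi = spec.center - spec.length / 2.0, spec.center + spec.length / 2.0
    if lo < -1e-9 or hi > seg.length + 1e-9:
        raise InvalidParameterError(
            f"lesion window [{lo:g}, {hi:g}] mm extends beyond segment "
            f"{spec.segment_id} (length {seg.length:g} mm)")
    u = (seg.arclengths - spec.center) / spec.length
    seg.radii = seg.radii * stenosis_multiplier(u, spec.severity, spec.profile)
    return out


def percent_diameter_stenosis(radii: np.ndarray,
                              arclengths: np.ndarray | None = None,
                              proximal_window: float = 10.0) -> float:
    """Anatomic severity DS% of a radius profile.

    DS = (1 - r_min / r_ref) * 100 with r_min the global minimum and r_ref
    the maximum radius within ``proximal_window`` mm proximal to r_min
    (falling back to the profile start when less is available).  A uniform
    profile returns 0.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size < 3:
        raise InvalidParameterError("radius profile needs >= 3 points")
    if arclengths is None:
        arclengths = np.arange(radii.size, dtype=float)
    arclengths = np.asarray(arclengths, dtype=float)
    i_min = int(np.argmin(radii))
    r_min = radii[i_min]
    s_min = arclengths[i_min]
    mask = (arclengths >= s_min - proximal_window) & (arclengths <= s_min)
    r_ref = float(np.max(radii[mask]))
    if r_ref <= 0:
        return 0.0
    return max(0.0, (1.0 - r_min / r_ref) * 100.0)


def segment_ds(seg: Segment, proximal_window: float = 10.0) -> float:
    """DS% of one segment's radius profile."""
    return percent_diameter_stenosis(seg.radii, seg.arclengths, proximal_window)


# ---------------------------------------------------------------------------
# synthetic tree generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeParams:
    """Parameters for one synthetic epicardial vessel.

    Defaults describe a generic left-anterior-descending-like artery:
    ~120 mm long, 1.9 mm inlet lumen radius, gentle taper, three side
    branches with daughter/parent radius ratio 0.8 (substantial side
    branches carry away much of the inlet flow, as septals/diagonals do).  Stenoses are given as
    (center arclength along the main vessel [mm], lesion length [mm],
    DS [%]) triples and applied via :func:`insert_stenosis`.
    """

    vessel_type: str = "LAD"
    total_length: float = 120.0
    inlet_radius: float = 1.9
    taper_rate: float = 0.004          # mm radius lost per mm length
    n_bifurcations: int = 3
    daughter_ratio: float = 0.8        # branch radius / local parent radius
    branch_length: float = 22.0
    stenoses: tuple[tuple[float, float, float], ...] = ()
    step: float = DEFAULT_STEP_MM
    min_radius: float = 0.3


def _main_curve(params: TreeParams, rng: np.random.Generator) -> np.ndarray:
    """Gently curved planar-ish main-vessel centerline, uniform in arclength."""
    n = max(2, int(math.ceil(params.total_length / params.step)) + 1)
    s = np.linspace(0.0, params.total_length, n)
    # curvature radius ~60-100 mm with a small out-of-plane component
    bend = rng.uniform(60.0, 100.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = s
    y = bend * (1.0 - np.cos(s / bend))
    z = 0.08 * bend * (1.0 - np.cos(s / bend + phase)) * np.sin(s / (2.0 * bend))
    pts = np.column_stack([x, y, z])
    # re-parameterize to uniform true arclength
    d = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    scale = params.total_length / d[-1]
    pts *= scale
    return pts


def generate_synthetic_tree(params: TreeParams, seed: int) -> CenterlineTree:
    """Build a seeded synthetic coronary tree.

    Deterministic for a fixed (params, seed).  The main vessel tapers
    linearly; side branches leave at quasi-uniform arclengths, avoiding any
    lesion window (lesions must sit within a single unbranched segment).
    The returned tree always passes :func:`validate_tree`.
    """
    if params.total_length <= 0 or params.inlet_radius <= 0 or params.step <= 0:
        raise InvalidParameterError("geometric parameters must be positive")
    tip_r = params.inlet_radius - params.taper_rate * params.total_length
    if tip_r <= params.min_radius:
        raise InvalidParameterError(
            f"taper leaves distal radius {tip_r:g} mm <= {params.min_radius} mm")
    for c, L, ds in params.stenoses:
        if not (0.0 <= ds < 100.0) or L <= 0:
            raise InvalidParameterError(f"bad stenosis spec ({c}, {L}, {ds})")
        if c - L / 2 < 1.0 or c + L / 2 > params.total_length - 1.0:
            raise InvalidParameterError("lesion window outside main vessel")

    rng = np.random.default_rng(seed)
    pts = _main_curve(params, rng)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    radii = params.inlet_radius - params.taper_rate * s

    # choose branch take-off arclengths away from lesion windows and the ends
    forbidden = [(c - L / 2 - 3.0, c + L / 2 + 3.0) for c, L, _ in params.stenoses]
    branch_s: list[float] = []
    if params.n_bifurcations > 0:
        targets = np.linspace(0.18, 0.72, params.n_bifurcations) * params.total_length
        for t in targets:
            t = t + rng.uniform(-4.0, 4.0)
            for lo, hi in forbidden:
                if lo < t < hi:
                    t = lo if abs(t - lo) < abs(t - hi) else hi
            t = float(np.clip(t, 5.0, params.total_length - 10.0))
            branch_s.append(t)
        branch_s.sort()

    # split the main polyline at branch take-offs (snap to nearest sample)
    cut_idx = sorted({int(np.argmin(np.abs(s - t))) for t in branch_s})
    cut_idx = [i for i in cut_idx if 0 < i < len(s) - 1]

    segments: dict[int, Segment] = {}
    next_id = 0
    bounds = [0] + cut_idx + [len(s) - 1]
    main_ids = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = Segment(next_id, pts[a:b + 1], radii[a:b + 1])
        segments[next_id] = seg
        main_ids.append(next_id)
        next_id += 1
    for prev, cur in zip(main_ids[:-1], main_ids[1:]):
        segments[cur].parent = prev
        segments[prev].children.append(cur)

    # side branches: straight, tapered, leaving at ~60 deg from local tangent
    for k, i in enumerate(cut_idx):
        parent_id = main_ids[k]
        origin = pts[i]
        tangent = pts[min(i + 1, len(s) - 1)] - pts[max(i - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        # pick a unit vector at ~60 degrees from the tangent
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, tangent)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        normal = np.cross(tangent, ref)
        normal /= np.linalg.norm(normal)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        side = math.cos(phi) * normal + math.sin(phi) * np.cross(tangent, normal)
        direction = math.cos(math.radians(60.0)) * tangent + \
            math.sin(math.radians(60.0)) * side
        direction /= np.linalg.norm(direction)
        r0 = params.daughter_ratio * radii[i]
        blen = params.branch_length * rng.uniform(0.85, 1.15)
        btaper = min(params.taper_rate, 0.6 * (r0 - params.min_radius) / blen)
        nb = max(2, int(math.ceil(blen / params.step)) + 1)
        bs = np.linspace(0.0, blen, nb)
        bpts = origin[None, :] + bs[:, None] * direction[None, :]
        bradii = r0 - btaper * bs
        seg = Segment(next_id, bpts, bradii, parent=parent_id)
        segments[next_id] = seg
        segments[parent_id].children.append(seg.id)
        next_id += 1

    outlets = sorted(sid for sid, seg in segments.items() if not seg.children)
    tree = CenterlineTree(segments, inlet=main_ids[0], outlets=outlets,
                          label=params.vessel_type)

    # apply lesions (translate main-vessel arclength to segment-local)
    seg_start = {}
    acc = 0.0
    for sid in main_ids:
        seg_start[sid] = acc
        acc += segments[sid].length
    for c, L, ds in params.stenoses:
        host = main_ids[-1]
        for sid in main_ids:
            if seg_start[sid] <= c <= seg_start[sid] + segments[sid].length:
                host = sid
                break
        tree = insert_stenosis(tree, StenosisSpec(host, c - seg_start[host], L, ds))

    bad = validate_tree(tree)
    if bad:  # pragma: no cover - generator contract
        raise InvalidParameterError("generator produced invalid tree: "
                                    + "; ".join(map(str, bad)))
    return tree


def main_path_location(tree: CenterlineTree, params: TreeParams,
                       global_arclength: float) -> tuple[int, float]:
    """Map an arclength along the generated main vessel to (segment, local s).

    Only meaningful for trees from :func:`generate_synthetic_tree`, whose
    main vessel is the chain of first children from the inlet.
    """
    sid = tree.inlet
    acc = 0.0
    while True:
        seg = tree.segments[sid]
        if global_arclength <= acc + seg.length or not seg.children:
            return sid, min(seg.length, max(0.0, global_arclength - acc))
        acc += seg.length
        # main continuation = the child whose first radius is largest
        sid = max(seg.children, key=lambda c: tree.segments[c].radii[0])


# ---------------------------------------------------------------------------
# serialization: ctifr-tree/1 JSON, legacy VTK polydata
# ---------------------------------------------------------------------------

def tree_to_dict(tree: CenterlineTree) -> dict:
    """Serialize to the versioned ``ctifr-tree/1`` mapping (units mm)."""
    return {
        "schema": TREE_SCHEMA,
        "label": tree.label,
        "inlet": tree.inlet,
        "outlets": list(tree.outlets),
        "segments": [
            {
                "id": sid,
                "parent": seg.parent,
                "points": [
                    {"x": float(p[0]), "y": float(p[1]), "z": float(p[2]),
                     "r": float(r)}
                    for p, r in zip(seg.points, seg.radii)
                ],
            }
            for sid, seg in sorted(tree.segments.items())
        ],
    }


def tree_from_dict(data: dict) -> CenterlineTree:
    """Parse a ``ctifr-tree/1`` mapping; raise SchemaError on any defect."""
    if not isinstance(data, dict):
        raise SchemaError("tree document must be a JSON object")
    if data.get("schema") != TREE_SCHEMA:
        raise SchemaError(f"unsupported schema {data.get('schema')!r}; "
                          f"expected {TREE_SCHEMA!r}")
    for key in ("inlet", "outlets", "segments"):
        if key not in data:
            raise SchemaError(f"missing required key {key!r}")
    segments: dict[int, Segment] = {}
    try:
        for sd in data["segments"]:
            pts = np.array([[p["x"], p["y"], p["z"]] for p in sd["points"]],
                           dtype=float)
            radii = np.array([p["r"] for p in sd["points"]], dtype=float)
            segments[int(sd["id"])] = Segment(int(sd["id"]), pts, radii,
                                              None if sd.get("parent") is None
                                              else int(sd["parent"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed segment record: {exc}") from exc
    for sid, seg in segments.items():
        if seg.parent is not None:
            if seg.parent not in segments:
                raise SchemaError(f"segment {sid} references missing parent {seg.parent}")
            segments[seg.parent].children.append(sid)
    for seg in segments.values():
        seg.children.sort()
    tree = CenterlineTree(segments, inlet=int(data["inlet"]),
                          outlets=[int(o) for o in data["outlets"]],
                          label=str(data.get("label", "unnamed")))
    bad = validate_tree(tree)
    if bad:
        raise SchemaError("tree violates invariants: " + "; ".join(map(str, bad)))
    return tree


def save_tree_json(tree: CenterlineTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1)
        fh.write("\n")


def load_tree_json(path) -> CenterlineTree:
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    return tree_from_dict(data)


def export_vtk_polyline(tree: CenterlineTree, path) -> None:
    """Write the tree as legacy-ASCII VTK polydata with radius point data.

    Visualization-only convenience (ParaView-compatible); nothing in the
    pipeline reads this format back.
    """
    sids = sorted(tree.segments)
    offsets, pts, radii = {}, [], []
    for sid in sids:
        seg = tree.segments[sid]
        offsets[sid] = len(pts)
        pts.extend(seg.points.tolist())
        radii.extend(seg.radii.tolist())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"ctifr centerline tree {tree.label}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        nlines = len(sids)
        size = sum(tree.segments[s].n_points + 1 for s in sids)
        fh.write(f"LINES {nlines} {size}\n")
        for sid in sids:
            seg = tree.segments[sid]
            ids = range(offsets[sid], offsets[sid] + seg.n_points)
            fh.write(f"{seg.n_points} " + " ".join(map(str, ids)) + "\n")
        fh.write(f"POINT_DATA {len(radii)}\nSCALARS radius float 1\n")
        fh.write("LOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.6f}\n")
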