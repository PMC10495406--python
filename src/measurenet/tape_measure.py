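"""Virtual tape measure: plane slicing and convex-wrap circumference extraction.

A physical tape pulled taut around a limb bridges concavities, so a tape
circumference is modeled as the perimeter of the 2D convex hull of the body
cross-section in the measurement plane. Cross-sections are obtained by
slicing the labeled triangle mesh with a plane; each closed intersection loop
carries the dominant semantic label of its source faces so that, e.g., a
waist plane that also cuts both arms still yields the torso loop.

Geometry is in meters internally; all returned circumferences are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .body_model import BodyMesh, Landmark
from .parts import PART_CLASSES, PART_GROUPS


@dataclass(frozen=True)
class Plane:
    origin: np.ndarray
    normal: np.ndarray

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.normal / np.linalg.norm(self.normal)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n @ helper) > 0.9:
            helper = np.array([0.0, 0.0, 1.0])
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class Loop:
    """One closed planar polyline with the dominant label of its faces."""

    points: np.ndarray          # (k, 3), ordered, implicitly closed
    label: int
    area: float                 # enclosed area in the slicing plane (m^2)

    def perimeter_mm(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum() * 1000.0)


@dataclass
class RingSlice:
    plane: Plane
    loops: list[Loop] = field(default_factory=list)  # descending enclosed area


def _assemble_loops(segments: np.ndarray, seg_labels: np.ndarray,
                    plane: Plane, tol: float) -> list[Loop]:
    """Chain unordered intersection segments into closed loops."""
    if len(segments) == 0:
        return []
    pts = segments.reshape(-1, 3)
    # quantize endpoints so identical points hash together
    keys = np.round(pts / tol).astype(np.int64)
    _, first, idx = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    coords = pts[first]
    edges = idx.reshape(-1, 2)
    # drop zero-length segments
    good = edges[:, 0] != edges[:, 1]
    edges, seg_labels = edges[good], seg_labels[good]

    adj: dict[int, list[tuple[int, int]]] = {}
    for e, (a, b) in enumerate(edges):
        adj.setdefault(int(a), []).append((int(b), e))
        adj.setdefault(int(b), []).append((int(a), e))

    used = np.zeros(len(edges), dtype=bool)
    loops = []
    u, v = plane.basis()
    for e0 in range(len(edges)):
        if used[e0]:
            continue
        start, cur = int(edges[e0, 0]), int(edges[e0, 1])
        used[e0] = True
        chain = [start, cur]
        chain_edges = [e0]
        while cur != start:
            nxt = None
            for nb, e in adj.get(cur, ()):
                if not used[e]:
                    nxt = (nb, e)
                    break
            if nxt is None:
                raise ValueError(
                    "open intersection chain: the sliced mesh component is not "
                    "closed (an edge is shared by fewer than two faces)"
                )
            used[nxt[1]] = True
            chain.append(nxt[0])
            chain_edges.append(nxt[1])
            cur = nxt[0]
        p3 = coords[chain[:-1]]
        p2 = np.stack([(p3 - plane.origin) @ u, (p3 - plane.origin) @ v], axis=1)
        x, y = p2[:, 0], p2[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        # dominant label = label with the largest total intersected length
        seg_len = np.linalg.norm(np.diff(coords[chain], axis=0), axis=1)
        labs = seg_labels[chain_edges].astype(np.int64)
        label = int(np.argmax(np.bincount(labs, weights=seg_len)))
        loops.append(Loop(points=p3, label=label, area=float(area)))
    loops.sort(key=lambda q: -q.area)
    return loops


def _plane_segments(vertices: np.ndarray, faces: np.ndarray,
                    labels: np.ndarray, vn: np.ndarray, offset: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized triangle/plane intersection.

    ``vn`` is the per-vertex projection onto the (unit) plane normal; the
    plane is {x : x.n = offset}. Assumes no vertex lies exactly on the plane
    (the caller nudges degenerate planes). Returns (segments (S,2,3),
    per-segment face labels (S,))."""
    df = vn[faces] - offset                   # (F, 3)
    npos = (df > 0).sum(axis=1)
    cross = (npos == 1) | (npos == 2)
    if not np.any(cross):
        return np.empty((0, 2, 3)), np.empty(0, dtype=labels.dtype)
    f = faces[cross]
    dfc = df[cross]
    segs = np.empty((len(f), 2, 3))
    slot = np.zeros(len(f), dtype=np.int64)
    for i, j in ((0, 1), (1, 2), (2, 0)):
        m = (dfc[:, i] > 0) != (dfc[:, j] > 0)
        if not np.any(m):
            continue
        t = dfc[m, i] / (dfc[m, i] - dfc[m, j])
        vi = vertices[f[m, i]]
        p = vi + t[:, None] * (vertices[f[m, j]] - vi)
        idx = np.nonzero(m)[0]
        segs[idx, slot[idx]] = p
        slot[idx] += 1
    return segs, labels[cross]


def slice_mesh(mesh: BodyMesh, plane: Plane,
               label_filter: frozenset[int] | None = None) -> RingSlice:
    """Intersect the mesh with a plane; returns closed loops, largest first.

    ``label_filter`` restricts slicing to faces with those labels, which both
    speeds up dense profiling and guarantees the returned loops belong to the
    requested body component. A plane that misses the mesh yields an empty
    slice.
    """
    nrm = np.asarray(plane.normal, dtype=float)
    if np.linalg.norm(nrm) == 0:
        raise ValueError("plane normal must be nonzero")
    nrm = nrm / np.linalg.norm(nrm)
    cache = getattr(mesh, "_slice_cache", None)
    if cache is None:
        cache = {}
        try:
            mesh._slice_cache = cache
        except AttributeError:
            pass
    key = None if label_filter is None else tuple(sorted(label_filter))
    if key in cache:
        faces, labels = cache[key]
    else:
        if label_filter is None:
            faces = mesh.faces
            labels = mesh.face_labels
        else:
            mask = np.isin(mesh.face_labels, list(label_filter))
            faces = mesh.faces[mask]
            labels = mesh.face_labels[mask]
        cache[key] = (faces, labels)
    if len(faces) == 0:
        return RingSlice(plane=Plane(plane.origin, nrm))

    nkey = ("vn", round(nrm[0], 12), round(nrm[1], 12), round(nrm[2], 12))
    if nkey in cache:
        vn = cache[nkey]
    else:
        vn = mesh.vertices @ nrm
        cache[nkey] = vn

    bbox = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    diag = float(np.linalg.norm(bbox))
    origin = np.asarray(plane.origin, dtype=float)
    offset = float(origin @ nrm)
    # nudge the plane if it passes (numerically) through vertices
    if np.min(np.abs(vn[faces.reshape(-1)] - offset)) < 1e-9 * diag:
        offset += 1e-7 * diag
        origin = origin + nrm * (1e-7 * diag)
    p = Plane(origin, nrm)
    segments, seg_labels = _plane_segments(mesh.vertices, faces, labels, vn,
                                           offset)
    if len(segments) == 0:
        return RingSlice(plane=p)
    loops = _assemble_loops(segments, seg_labels, p, tol=1e-9 * diag)
    return RingSlice(plane=p, loops=loops)


def _resolve_group(part) -> frozenset[int]:
    if isinstance(part, str):
        if part in PART_GROUPS:
            return PART_GROUPS[part]
        raise KeyError(f"unknown part group {part!r}; known: {sorted(PART_GROUPS)}")
    return frozenset(int(p) for p in part)


def convex_wrap_length(ring: RingSlice, part) -> float:
    """Tape length (mm) around the largest loop carrying the requested label.

    ``part`` is a group name ('torso', 'left_leg', ...) or an explicit set of
    label ids. The loop is projected into the slicing plane and wrapped with
    its 2D convex hull.
    """
    group = _resolve_group(part)
    candidates = [lp for lp in ring.loops if lp.label in group]
    if not candidates:
        avail = sorted({PART_CLASSES.get(lp.label, str(lp.label))
                        for lp in ring.loops})
        raise ValueError(
            f"no cross-section loop with labels {sorted(group)}; "
            f"available loops: {avail or 'none'}"
        )
    loop = candidates[0]  # loops are ordered by descending area
    u, v = ring.plane.basis()
    rel = loop.points - ring.plane.origin
    p2 = np.stack([rel @ u, rel @ v], axis=1)
    if len(p2) < 3:
        return loop.perimeter_mm()
    hull = ConvexHull(p2)
    hp = p2[hull.vertices]
    d = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum() * 1000.0)


@dataclass
class MeasurementSet:
    """Named circumferences (mm), optional 112-ring dense profile, and WHR."""

    named: dict[str, float]
    whr: float
    dense: np.ndarray | None = None
    ring_map: list[tuple[str, float]] | None = None

    def __getitem__(self, key: str) -> float:
        return self.named[key]

    def as_dict(self) -> dict[str, float]:
        out = dict(self.named)
        out["whr"] = self.whr
        return out


def compute_whr(waist: float, hip: float) -> float:
    """Waist-to-hip circumference ratio."""
    if hip <= 0:
        raise ValueError("hip circumference must be > 0")
    return waist / hip


def measure_landmark(mesh: BodyMesh, lm: Landmark) -> float:
    ring = slice_mesh(mesh, Plane(lm.origin, lm.normal),
                      label_filter=PART_GROUPS[lm.part_group])
    return convex_wrap_length(ring, lm.part_group)


def named_measurements(mesh: BodyMesh, dense: bool = False,
                       n_rings: int = 112) -> MeasurementSet:
    """Measure the six named circumferences (and optionally the dense profile).

    Torso circumferences are taken on the torso loop at the landmark planes;
    thigh/calf on the designated (left) leg; bicep perpendicular to the left
    arm axis. WHR is waist/hip.
    """
    required = ["hip", "waist", "chest", "thigh", "calf", "bicep"]
    missing = [n for n in required if n not in mesh.landmarks]
    if missing:
        raise ValueError(f"mesh is missing landmark(s): {missing}")
    named = {n: measure_landmark(mesh, mesh.landmarks[n]) for n in required}
    whr = compute_whr(named["waist"], named["hip"])
    if not dense:
        return MeasurementSet(named=named, whr=whr)
    dv, rm = dense_ring_profile(mesh, n_rings=n_rings)
    return MeasurementSet(named=named, whr=whr, dense=dv, ring_map=rm)


def _ring_plan(mesh: BodyMesh, n_rings: int) -> list[tuple[str, Landmark]]:
    """Allocate rings over the body; landmark stations are grid points.

    Default 112-ring layout: 56 torso rings spanning hip-to-chest +/- 20%,
    20 per leg (calf-to-thigh span) and 8 per arm (from the bicep station
    down the arm axis).
    """
    if n_rings < 6:
        raise ValueError("n_rings must be >= 6")
    lm = mesh.landmarks
    up = np.array([0.0, 1.0, 0.0])

    n_torso = max(3, round(n_rings * 56 / 112))
    n_leg = max(1, round(n_rings * 20 / 112))
    n_arm = max(1, round(n_rings * 8 / 112))
    n_torso = n_rings - 2 * n_leg - 2 * n_arm  # torso absorbs rounding

    y_hip = float(lm["hip"].origin[1])
    y_waist = float(lm["waist"].origin[1])
    y_chest = float(lm["chest"].origin[1])
    span = y_chest - y_hip
    lo, hi = y_hip - 0.2 * span, y_chest + 0.2 * span
    # keep the extended span inside the torso component
    tmask = np.isin(mesh.face_labels, list(PART_GROUPS["torso"]))
    ty = mesh.vertices[np.unique(mesh.faces[tmask])][:, 1]
    lo = max(lo, float(ty.min()) + 0.02 * (float(ty.max()) - float(ty.min())))
    hi = min(hi, float(ty.max()) - 0.02 * (float(ty.max()) - float(ty.min())))
    # piecewise grids so hip/waist/chest are hit exactly (as grid starts)
    n_free = n_torso - 1  # total grid points = segment counts + final endpoint
    seg = np.array([y_hip - lo, y_waist - y_hip, y_chest - y_waist, hi - y_chest])
    counts = np.maximum(1, np.round(n_free * seg / seg.sum()).astype(int))
    while counts.sum() > n_free:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_free:
        counts[np.argmin(counts)] += 1
    edges = [lo, y_hip, y_waist, y_chest, hi]
    ys: list[float] = []
    for i in range(4):
        pts = np.linspace(edges[i], edges[i + 1], counts[i], endpoint=False)
        ys.extend(pts.tolist())
    ys.append(hi)
    plan = [("torso", Landmark(np.array([0.0, y, 0.0]), up, "torso"))
            for y in ys]

    y_calf = float(lm["calf"].origin[1])
    y_thigh = float(lm["thigh"].origin[1])
    for side in ("left", "right"):
        x = float(lm["thigh"].origin[0]) * (1 if side == "left" else -1)
        for y in np.linspace(y_calf, y_thigh, n_leg):
            plan.append((f"{side}_leg",
                         Landmark(np.array([x, float(y), 0.0]), up, f"{side}_leg")))

    b = lm["bicep"]
    for side in ("left", "right"):
        refl = np.array([1.0, 1.0, 1.0]) if side == "left" \
            else np.array([-1.0, 1.0, 1.0])
        o = b.origin * refl
        nvec = b.normal * refl
        for k in range(n_arm):
            t = 0.12 * mesh.height * k / max(n_arm - 1, 1)
            plan.append((f"{side}_arm",
                         Landmark(o + nvec * t, nvec, f"{side}_arm")))
    return plan


def dense_ring_profile(mesh: BodyMesh,
                       n_rings: int = 112) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Circumference (mm) at ``n_rings`` planes distributed over the body.

    Returns (values, ring_map) where ring_map[i] = (part group, station): the
    station is the normalized height for horizontal rings or the axial offset
    for arm rings. The named landmark stations coincide with specific rings at
    the default allocation.
    """
    plan = _ring_plan(mesh, n_rings)
    # the torso count absorbed rounding; trim or pad from the torso segment
    values = np.empty(len(plan))
    ring_map: list[tuple[str, float]] = []
    for i, (group, lmk) in enumerate(plan):
        ring = slice_mesh(mesh, Plane(lmk.origin, lmk.normal),
                          label_filter=PART_GROUPS[group])
        try:
            values[i] = convex_wrap_length(ring, group)
        except ValueError as exc:
            raise ValueError(f"ring {i} ({group}) misses its part: {exc}") from exc
        station = float(lmk.origin[1]) / mesh.height
        ring_map.append((group, station))
    if len(values) != n_rings:
        raise AssertionError(
            f"ring allocation produced {len(values)} rings, expected {n_rings}")
    return values, ring_map
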