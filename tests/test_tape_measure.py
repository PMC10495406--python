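"""Geometry of the virtual tape measure: slicing, convex wrap, profiles."""

import math

import numpy as np
import pytest

from measurenet.body_model import BodyMesh, Landmark
from measurenet.parts import PART_IDS
from measurenet.tape_measure import (Loop, Plane, RingSlice, compute_whr,
                                     convex_wrap_length, dense_ring_profile,
                                     named_measurements, slice_mesh)

from conftest import (REQUESTED, cylinder_mesh, gift_wrap_hull,
                       polygon_perimeter)


def _box_mesh():
    """Unit cube [0,1]^3 labeled as torso-waist."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
        [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
        [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
    ])
    lab = np.full(len(f), PART_IDS["waist"], dtype=np.int16)
    return BodyMesh(vertices=v, faces=f, face_labels=lab, landmarks={},
                    points={}, height=1.0)


def test_cube_mid_slice_is_unit_square():
    mesh = _box_mesh()
    ring = slice_mesh(mesh, Plane(np.array([0, 0.5, 0.0]),
                                  np.array([0.0, 1.0, 0.0])))
    assert len(ring.loops) == 1
    assert convex_wrap_length(ring, "torso") == pytest.approx(4000.0, rel=1e-9)


@pytest.mark.parametrize("sections", [64, 128])
def test_cylinder_matches_chord_perimeter(sections):
    r = 0.2
    mesh = cylinder_mesh(radius=r, sections=sections)
    ring = slice_mesh(mesh, Plane(np.array([0, 0.5, 0.0]),
                                  np.array([0.0, 1.0, 0.0])))
    expected = 2 * sections * r * math.sin(math.pi / sections) * 1000
    assert convex_wrap_length(ring, "torso") == pytest.approx(expected,
                                                              rel=1e-9)


def test_cylinder_discretization_error_decreases_monotonically():
    r = 0.15
    errors = []
    for sections in (32, 64, 128, 256):
        mesh = cylinder_mesh(radius=r, sections=sections)
        c = convex_wrap_length(
            slice_mesh(mesh, Plane(np.array([0, 0.5, 0]),
                                   np.array([0.0, 1.0, 0.0]))), "torso")
        errors.append(abs(c - 2 * math.pi * r * 1000) / (2 * math.pi * r * 1000))
    assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))
    assert errors[-1] < 0.005


def test_slice_through_both_legs_yields_two_labeled_loops(male_mesh):
    y = 0.18 * male_mesh.height  # calf height
    ring = slice_mesh(male_mesh, Plane(np.array([0.0, y, 0.0]),
                                       np.array([0.0, 1.0, 0.0])))
    labels = {lp.label for lp in ring.loops}
    assert PART_IDS["lower_left_leg"] in labels
    assert PART_IDS["lower_right_leg"] in labels


def test_plane_missing_mesh_returns_empty_slice(male_mesh):
    ring = slice_mesh(male_mesh, Plane(np.array([0.0, 99.0, 0.0]),
                                       np.array([0.0, 1.0, 0.0])))
    assert ring.loops == []


def test_open_mesh_raises_descriptive_error():
    mesh = _box_mesh()
    mesh.faces = mesh.faces[:-1]  # puncture the cube
    mesh.face_labels = mesh.face_labels[:-1]
    with pytest.raises(ValueError, match="not.*closed|open"):
        slice_mesh(mesh, Plane(np.array([0, 0.5, 0]),
                               np.array([0.0, 1.0, 0.0])))


def _planar_slice(points_2d, label=PART_IDS["waist"]):
    pts3 = np.column_stack([points_2d[:, 0],
                            np.zeros(len(points_2d)), points_2d[:, 1]])
    loop = Loop(points=pts3, label=label, area=1.0)
    plane = Plane(np.zeros(3), np.array([0.0, 1.0, 0.0]))
    return RingSlice(plane=plane, loops=[loop])


def test_convex_loop_hull_equals_raw_perimeter():
    t = np.linspace(0, 2 * np.pi, 73)[:-1]
    pts = np.stack([0.3 * np.cos(t), 0.18 * np.sin(t)], axis=1)
    ring = _planar_slice(pts)
    raw = ring.loops[0].perimeter_mm()
    assert convex_wrap_length(ring, "torso") == pytest.approx(raw, rel=1e-9)


def test_star_loop_hull_shorter_and_matches_giftwrap_oracle():
    t = np.linspace(0, 2 * np.pi, 11)[:-1]
    radii = np.where(np.arange(10) % 2 == 0, 0.3, 0.12)
    pts = np.stack([radii * np.cos(t), radii * np.sin(t)], axis=1)
    ring = _planar_slice(pts)
    raw = ring.loops[0].perimeter_mm()
    hull_len = convex_wrap_length(ring, "torso")
    assert hull_len < raw
    oracle = polygon_perimeter(gift_wrap_hull(pts)) * 1000
    assert hull_len == pytest.approx(oracle, abs=1e-9 * oracle)


def test_hull_invariant_under_collinear_points():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    with_collinear = np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1],
                               [0.5, 1], [0, 1], [0, 0.5]])
    a = convex_wrap_length(_planar_slice(square), "torso")
    b = convex_wrap_length(_planar_slice(with_collinear), "torso")
    assert a == pytest.approx(b, rel=1e-9)


@pytest.mark.parametrize("seed", range(4))
def test_hull_property_on_random_cross_sections(seed):
    """Hull <= raw for concave loops; == for convex; matches the oracle."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 2 * np.pi, 60))
    # concave: jagged radii
    r_concave = 0.2 + 0.1 * rng.uniform(-1, 1, 60)
    pts = np.stack([r_concave * np.cos(t), r_concave * np.sin(t)], axis=1)
    ring = _planar_slice(pts)
    hull_len = convex_wrap_length(ring, "torso")
    assert hull_len <= ring.loops[0].perimeter_mm() + 1e-9
    oracle = polygon_perimeter(gift_wrap_hull(pts)) * 1000
    assert hull_len == pytest.approx(oracle, abs=1e-6)


def test_missing_label_error_lists_available(male_mesh):
    y = 0.18 * male_mesh.height
    ring = slice_mesh(male_mesh, Plane(np.array([0.0, y, 0.0]),
                                       np.array([0.0, 1.0, 0.0])))
    with pytest.raises(ValueError, match="available"):
        convex_wrap_length(ring, "head")


def test_named_measurements_roundtrip_and_whr(male_mesh):
    ms = named_measurements(male_mesh)
    for k, v in REQUESTED.items():
        assert ms.named[k] == pytest.approx(v, rel=0.01)
    assert ms.whr == pytest.approx(900.0 / 1000.0, rel=0.01)
    assert ms.whr == pytest.approx(ms.named["waist"] / ms.named["hip"],
                                   abs=1e-9)


def test_uniform_scaling_scales_circumferences_not_whr(male_mesh):
    ms = named_measurements(male_mesh)
    s = 1.3
    scaled = BodyMesh(
        vertices=male_mesh.vertices * s, faces=male_mesh.faces.copy(),
        face_labels=male_mesh.face_labels.copy(),
        landmarks={k: Landmark(v.origin * s, v.normal, v.part_group)
                   for k, v in male_mesh.landmarks.items()},
        points={k: v * s for k, v in male_mesh.points.items()},
        height=male_mesh.height * s)
    ms2 = named_measurements(scaled)
    for k in ms.named:
        assert ms2.named[k] == pytest.approx(s * ms.named[k], rel=1e-9)
    assert ms2.whr == pytest.approx(ms.whr, abs=1e-6)


def test_rigid_motion_leaves_circumferences_invariant(male_mesh):
    ms = named_measurements(male_mesh)
    theta = 0.7
    rot = np.array([[math.cos(theta), 0, math.sin(theta)],
                    [0, 1, 0],
                    [-math.sin(theta), 0, math.cos(theta)]])
    tilt = 0.3
    rot2 = np.array([[1, 0, 0],
                     [0, math.cos(tilt), -math.sin(tilt)],
                     [0, math.sin(tilt), math.cos(tilt)]])
    m = np.eye(4)
    m[:3, :3] = rot2 @ rot
    m[:3, 3] = [0.5, -0.2, 1.1]
    moved = male_mesh.transform(m)
    ms2 = named_measurements(moved)
    for k in ms.named:
        assert ms2.named[k] == pytest.approx(ms.named[k], rel=1e-6)


def test_dense_profile_layout_and_landmark_coincidence(male_mesh):
    values, ring_map = dense_ring_profile(male_mesh, n_rings=112)
    assert len(values) == 112 and len(ring_map) == 112
    assert np.all(values > 0)
    ms = named_measurements(male_mesh)
    stations = {"hip": 0.53, "waist": 0.63, "chest": 0.72}
    for name, st in stations.items():
        idx = [i for i, (g, s) in enumerate(ring_map)
               if g == "torso" and abs(s - st) < 1e-9]
        assert len(idx) == 1
        assert values[idx[0]] == pytest.approx(ms.named[name], abs=1e-9)
    # ring-group allocation: 56 torso / 20 per leg / 8 per arm
    groups = [g for g, _ in ring_map]
    assert groups.count("torso") == 56
    assert groups.count("left_leg") == groups.count("right_leg") == 20
    assert groups.count("left_arm") == groups.count("right_arm") == 8


def test_optimal_ring_alignment_finds_ring_near_waist(male_mesh):
    """Emulates aligning an external tape value to the closest dense ring."""
    values, ring_map = dense_ring_profile(male_mesh, n_rings=112)
    external_waist = REQUESTED["waist"] + 6.0  # a slightly offset tape value
    torso = [(i, s) for i, (g, s) in enumerate(ring_map) if g == "torso"]
    best = min(torso, key=lambda p: abs(values[p[0]] - external_waist))
    waist_idx = [i for i, (g, s) in enumerate(ring_map)
                 if g == "torso" and abs(s - 0.63) < 1e-9][0]
    waist_pos = [j for j, (i, _) in enumerate(torso) if i == waist_idx][0]
    best_pos = [j for j, (i, _) in enumerate(torso) if i == best[0]][0]
    assert abs(best_pos - waist_pos) <= 3


def test_compute_whr():
    assert compute_whr(850.0, 1000.0) == pytest.approx(0.85)
    assert compute_whr(900.0, 900.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_whr(900.0, 0.0)
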