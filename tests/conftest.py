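import numpy as np
import pytest

from measurenet.body_model import (BodyMesh, build_mesh,
                                   shape_from_measurements)
from measurenet.parts import PART_IDS

REQUESTED = {"hip": 1000.0, "waist": 900.0, "chest": 1030.0,
             "thigh": 580.0, "calf": 385.0, "bicep": 330.0}


@pytest.fixture(scope="session")
def male_params():
    return shape_from_measurements(REQUESTED, "male", 1.75)


@pytest.fixture(scope="session")
def male_mesh(male_params):
    return build_mesh(male_params)


def quick_subjects(sex: str, n: int, seed: int):
    """Fast cohort: sample the population spec directly (no mixture pipeline)."""
    from measurenet.body_model import (MEASUREMENT_NAMES, DEFAULT_BOUNDS,
                                       Subject, default_population)

    spec = default_population(sex)
    rng = np.random.default_rng(seed)
    table = spec.sample(n, rng)
    subjects = []
    for i, row in table.iterrows():
        meas = {m: float(np.clip(row[m], DEFAULT_BOUNDS[m][0] * 1.01,
                                 DEFAULT_BOUNDS[m][1] * 0.99))
                for m in MEASUREMENT_NAMES}
        height = float(np.clip(row["height"], 1.25, 2.15))
        aspects = {p: float(np.clip(rng.normal(spec.aspect_mean, spec.aspect_sd),
                                    0.55, 1.0))
                   for p in ("torso", "leg", "arm")}
        params = shape_from_measurements(meas, sex, height, aspects=aspects)
        subjects.append(Subject(int(row["subject_id"]), sex, height, meas,
                                params))
    return subjects


@pytest.fixture(scope="session")
def small_cohort():
    """~30 quick male subjects rendered once each (shared across tests)."""
    from measurenet.dataset import examples_from_subjects

    subjects = quick_subjects("male", 30, seed=100)
    return examples_from_subjects(subjects, seed=101)


def cylinder_mesh(radius: float = 0.15, height: float = 1.0,
                  sections: int = 64, label: int = PART_IDS["waist"]
                  ) -> BodyMesh:
    """Right circular cylinder (approximated by a prism), axis = y."""
    import math

    from measurenet.body_model import Landmark

    theta = 2 * math.pi * np.arange(sections) / sections
    ring = np.stack([radius * np.cos(theta), np.zeros(sections),
                     radius * np.sin(theta)], axis=1)
    verts = np.vstack([ring, ring + np.array([0, height, 0]),
                       [[0, 0, 0]], [[0, height, 0]]])
    faces, labels = [], []
    for j in range(sections):
        jn = (j + 1) % sections
        faces += [(j, jn, sections + j), (jn, sections + jn, sections + j)]
        faces += [(2 * sections, jn, j),
                  (2 * sections + 1, sections + j, sections + jn)]
        labels += [label] * 4
    landmarks = {"waist": Landmark(np.array([0.0, height / 2, 0.0]),
                                   np.array([0.0, 1.0, 0.0]), "torso")}
    return BodyMesh(vertices=verts, faces=np.array(faces, dtype=np.int64),
                    face_labels=np.array(labels, dtype=np.int16),
                    landmarks=landmarks, points={}, height=height)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never reuse library code paths)
# ---------------------------------------------------------------------------

def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """O(n*h) gift-wrapping convex hull of 2-D points; returns hull vertices
    in order."""
    pts = np.asarray(points, dtype=float)
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    hull = [start]
    while True:
        cur = hull[-1]
        cand = 0 if cur != 0 else 1
        for i in range(len(pts)):
            if i == cur:
                continue
            u = pts[cand] - pts[cur]
            w = pts[i] - pts[cur]
            cross = u[0] * w[1] - u[1] * w[0]
            if cand == cur or cross < -1e-15 or (
                    abs(cross) <= 1e-15 and
                    np.linalg.norm(pts[i] - pts[cur]) >
                    np.linalg.norm(pts[cand] - pts[cur])):
                cand = i
        if cand == start:
            break
        hull.append(cand)
        cur = cand
    return pts[hull]


def polygon_perimeter(pts: np.ndarray) -> float:
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def brute_percentile_linear(values, q: float) -> float:
    """Linear-interpolation percentile, written out longhand."""
    srt = sorted(float(v) for v in values)
    pos = (q / 100.0) * (len(srt) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return srt[lo] * (1 - frac) + srt[hi] * frac


def eq1_scalar(task_losses, weights) -> float:
    """Direct evaluation of the uncertainty-weighted total loss."""
    import math

    return sum(li / wi + math.log(1.0 + wi)
               for li, wi in zip(task_losses, weights))
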