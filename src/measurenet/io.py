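"""File formats: labeled meshes (OBJ/PLY + label sidecar), segmentation PNGs,
manifests and example metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from PIL import Image

from .body_model import BodyMesh, Landmark
from .parts import PALETTE
from .render import MultiViewExample, SegmentationImage


def save_mesh(mesh: BodyMesh, path) -> None:
    """Write geometry as OBJ (or PLY with an integer 'part' face property),
    face labels as a sidecar CSV, and landmarks/points as a sidecar JSON."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    if path.suffix.lower() == ".ply":
        tm.metadata["_ply_raw"] = {}
        # trimesh has no first-class custom face property API for PLY export;
        # labels are written in the sidecar either way
        tm.export(path)
    else:
        tm.export(path, file_type="obj", include_normals=False,
                  include_texture=False)
    pd.DataFrame({"face_index": np.arange(len(mesh.faces)),
                  "part": mesh.face_labels}).to_csv(
        path.with_suffix(path.suffix + ".labels.csv"), index=False)
    meta = {
        "height": mesh.height,
        "landmarks": {
            k: {"origin": v.origin.tolist(), "normal": v.normal.tolist(),
                "part_group": v.part_group}
            for k, v in mesh.landmarks.items()
        },
        "points": {k: v.tolist() for k, v in mesh.points.items()},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def load_mesh(path) -> BodyMesh:
    """Load a labeled mesh saved by :func:`save_mesh`.

    Raises a descriptive error when the label sidecar is missing, since a
    bare OBJ carries no part information.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".labels.csv")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{sidecar} not found: labeled meshes require a sidecar CSV with "
            "columns face_index,part mapping every face to a part class id"
        )
    tm = trimesh.load(path, process=False, force="mesh")
    labels_df = pd.read_csv(sidecar)
    labels = np.zeros(len(tm.faces), dtype=np.int16)
    labels[labels_df["face_index"].to_numpy()] = labels_df["part"].to_numpy()
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    landmarks: dict[str, Landmark] = {}
    points: dict[str, np.ndarray] = {}
    verts = np.asarray(tm.vertices, dtype=float)
    height = float(verts[:, 1].max())
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        height = float(meta.get("height", height))
        for k, v in meta.get("landmarks", {}).items():
            landmarks[k] = Landmark(np.array(v["origin"]),
                                    np.array(v["normal"]), v["part_group"])
        points = {k: np.array(v) for k, v in meta.get("points", {}).items()}
    return BodyMesh(vertices=verts,
                    faces=np.asarray(tm.faces, dtype=np.int64),
                    face_labels=labels, landmarks=landmarks, points=points,
                    height=height)


def save_segmentation_png(img: SegmentationImage, path) -> None:
    """Indexed-color PNG with the package's fixed part palette."""
    im = Image.fromarray(img.data.astype(np.uint8), mode="P")
    flat = [c for rgb in PALETTE for c in rgb]
    im.putpalette(flat + [0] * (768 - len(flat)))
    im.save(path)


def load_segmentation_png(path, view: str = "front") -> SegmentationImage:
    im = Image.open(path)
    return SegmentationImage(np.array(im, dtype=np.uint8), view=view)


def save_example(example: MultiViewExample, directory) -> None:
    """Write one example: per-view PNGs plus a JSON of scalars and targets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for view, img in example.images.items():
        save_segmentation_png(img, directory / f"{view}.png")
    meta = {
        "subject_id": example.subject_id,
        "sex": example.sex,
        "height": example.height,
        "weight": example.weight,
        "targets": {
            "named": example.targets.named,
            "whr": example.targets.whr,
            "dense": (example.targets.dense.tolist()
                      if example.targets.dense is not None else None),
        },
        "shape_vector": example.shape_vector.tolist(),
        "cameras": {
            v: {"position": c.position.tolist(),
                "angles_deg": c.angles_deg.tolist(),
                "focal_px": c.focal_px}
            for v, c in example.cameras.items()
        },
    }
    (directory / "example.json").write_text(json.dumps(meta, indent=1))
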