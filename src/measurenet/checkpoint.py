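"""Checkpoint directories: config snapshot (YAML), weights (npz), history CSV."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import MeasureNet, NetConfig, TargetScaler


def save_checkpoint(model: MeasureNet, history: pd.DataFrame, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["resolution"] = list(cfg["resolution"])
    cfg["whr_bins"] = list(cfg["whr_bins"])
    (directory / "config.yaml").write_text(yaml.safe_dump(cfg))
    arrays = dict(model.state_dict())
    arrays["cls_temperature"] = np.array([model.cls_temperature])
    arrays["cls_affine"] = np.array(model.cls_affine)
    sc = model.scaler
    if sc is not None:
        arrays |= {
            "scaler/dense_mean": sc.dense_mean, "scaler/dense_sd": sc.dense_sd,
            "scaler/named_mean": sc.named_mean, "scaler/named_sd": sc.named_sd,
            "scaler/whr": np.array([sc.whr_mean, sc.whr_sd]),
            "scaler/shape_mean": sc.shape_mean, "scaler/shape_sd": sc.shape_sd,
        }
    np.savez(directory / "weights.npz", **arrays)
    history.to_csv(directory / "history.csv", index=False)
    return directory


def load_checkpoint(directory) -> tuple[MeasureNet, pd.DataFrame]:
    directory = Path(directory)
    cfg_d = yaml.safe_load((directory / "config.yaml").read_text())
    cfg_d["resolution"] = tuple(cfg_d["resolution"])
    cfg_d["whr_bins"] = tuple(cfg_d["whr_bins"])
    model = MeasureNet(NetConfig(**cfg_d))
    with np.load(directory / "weights.npz") as z:
        arrays = {k: z[k] for k in z.files}
    model.cls_temperature = float(arrays.pop("cls_temperature", [1.0])[0])
    aff = arrays.pop("cls_affine", np.array([1.0, 0.0]))
    model.cls_affine = (float(aff[0]), float(aff[1]))
    state = {k: v for k, v in arrays.items() if not k.startswith("scaler/")}
    model.load_state_dict(state)
    if "scaler/dense_mean" in arrays:
        whr = arrays["scaler/whr"]
        model.scaler = TargetScaler(
            arrays["scaler/dense_mean"], arrays["scaler/dense_sd"],
            arrays["scaler/named_mean"], arrays["scaler/named_sd"],
            float(whr[0]), float(whr[1]),
            arrays["scaler/shape_mean"], arrays["scaler/shape_sd"],
        )
    history = pd.read_csv(directory / "history.csv")
    return model, history
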