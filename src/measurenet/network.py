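"""Multi-view multi-task regressor for circumferences and waist-to-hip ratio.

Architecture (desk scale): each segmentation view is one-hot encoded and
featurized by a small residual convolutional backbone with squeeze-excitation
channel attention and Swish activations; per-view features are concatenated
with normalized height/weight/sex scalars, passed through a four-block
residual fully connected trunk, a self-attention block over learned feature
tokens, and task heads:

* 112 dense ring circumferences (standardized regression)
* six named circumferences (standardized regression)
* WHR by regression and by soft-binned classification (60 bins on [0.6, 1.2])
* a body-shape parameter vector (regularizer; also the decoder input for the
  shape-decode prediction mode)

The total training loss is the uncertainty-weighted multi-task sum
``L = sum_i L_i / w_i + log(1 + w_i)`` with one learned positive weight per
task, so task importance is tuned automatically rather than by hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .parts import N_CLASSES
from .render import MultiViewExample

VIEW_SETS = {1: ("front",), 2: ("front", "side"), 3: ("front", "side", "back")}


@dataclass
class NetConfig:
    views: int = 3
    width_mult: float = 1.0
    activation: str = "swish"
    use_squeeze_excitation: bool = True
    use_self_attention: bool = True
    mode: str = "direct"            # 'direct' or 'shape-decode'
    body_centric_crop: bool = True  # crop/rescale each view to the body box
    sex_specific: bool = True
    whr_bins: tuple[float, float, int] = (0.6, 1.2, 60)
    predict_pose: bool = False
    predict_camera: bool = False
    lr: float = 2e-3
    epochs: int = 8
    batch_size: int = 24
    resolution: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.views not in VIEW_SETS:
            raise ValueError("views must be 1, 2 or 3")
        if self.mode not in ("direct", "shape-decode"):
            raise ValueError("mode must be 'direct' or 'shape-decode'")
        if self.activation not in ("swish", "relu"):
            raise ValueError("activation must be 'swish' or 'relu'")
        lo, hi, n = self.whr_bins
        if not (lo < hi and n >= 2):
            raise ValueError("whr_bins must be (lo, hi, n) with lo < hi, n >= 2")

    @property
    def view_names(self) -> tuple[str, ...]:
        return VIEW_SETS[self.views]

    def bin_centers(self) -> np.ndarray:
        lo, hi, n = self.whr_bins
        edges = np.linspace(lo, hi, n + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class Prediction:
    """Raw network outputs for one example (physical units)."""

    dense: np.ndarray
    named: dict[str, float]
    whr_regression: float
    whr_class_probabilities: np.ndarray
    shape_estimate: np.ndarray
    whr_final: float | None = None
    pose_estimate: np.ndarray | None = None
    camera_estimate: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _act(x: Tensor, kind: str) -> Tensor:
    return ad.swish(x) if kind == "swish" else ad.relu(x)


class _ParamStore:
    """Flat registry of named parameters."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: dict[str, Tensor] = {}

    def weight(self, name: str, shape: tuple, fan_in: int) -> Tensor:
        if name not in self.params:
            w = self.rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
            self.params[name] = Tensor(w.astype(np.float32), requires_grad=True)
        return self.params[name]

    def zeros(self, name: str, shape: tuple) -> Tensor:
        if name not in self.params:
            self.params[name] = Tensor(np.zeros(shape, dtype=np.float32),
                                       requires_grad=True)
        return self.params[name]

    def const(self, name: str, value: np.ndarray) -> Tensor:
        if name not in self.params:
            self.params[name] = Tensor(value.astype(np.float32),
                                       requires_grad=True)
        return self.params[name]


def _linear(ps: _ParamStore, name: str, x: Tensor, n_in: int, n_out: int) -> Tensor:
    w = ps.weight(f"{name}.w", (n_in, n_out), n_in)
    b = ps.zeros(f"{name}.b", (n_out,))
    return ad.add(ad.matmul(x, w), b)


def _conv(ps: _ParamStore, name: str, x: Tensor, c_in: int, c_out: int,
          k: int, stride: int) -> Tensor:
    w = ps.weight(f"{name}.w", (c_out, c_in, k, k), c_in * k * k)
    b = ps.zeros(f"{name}.b", (c_out,))
    return ad.conv2d(x, w, b, stride=stride, pad=k // 2)


def _se_block(ps: _ParamStore, name: str, x: Tensor, channels: int,
              act: str, reduction: int = 4) -> Tensor:
    """Squeeze-excitation: global pool -> bottleneck MLP -> channel gates."""
    hidden = max(channels // reduction, 4)
    z = ad.global_avg_pool(x)                       # (N, C)
    z = _act(_linear(ps, f"{name}.fc1", z, channels, hidden), act)
    gate = ad.sigmoid(_linear(ps, f"{name}.fc2", z, hidden, channels))
    gate = ad.reshape(gate, (gate.shape[0], channels, 1, 1))
    return ad.mul(x, gate)


def _res_conv_block(ps: _ParamStore, name: str, x: Tensor, c_in: int,
                    c_out: int, stride: int, act: str, use_se: bool,
                    record=None) -> Tensor:
    h = _conv(ps, f"{name}.conv1", x, c_in, c_out, 3, stride)
    if record is not None:
        record.append(h)
    h = _act(h, act)
    h = _conv(ps, f"{name}.conv2", h, c_out, c_out, 3, 1)
    if use_se:
        h = _se_block(ps, f"{name}.se", h, c_out, act)
    if stride != 1 or c_in != c_out:
        skip = _conv(ps, f"{name}.proj", x, c_in, c_out, 1, stride)
    else:
        skip = x
    out = ad.add(h, skip)
    if record is not None:
        record.append(out)
    return _act(out, act)


def _res_fc_block(ps: _ParamStore, name: str, x: Tensor, dim: int, act: str,
                  record=None) -> Tensor:
    h = _linear(ps, f"{name}.fc1", x, dim, dim)
    if record is not None:
        record.append(h)
    h = _act(h, act)
    h = _linear(ps, f"{name}.fc2", h, dim, dim)
    out = ad.add(h, x)
    if record is not None:
        record.append(out)
    return _act(out, act)


def _self_attention(ps: _ParamStore, name: str, x: Tensor, tokens: int,
                    dim: int) -> Tensor:
    """Single-head scaled dot-product attention over feature tokens.

    x: (N, T*d) reshaped to (N, T, d); output re-flattened, residual added.
    """
    n = x.shape[0]
    t3 = ad.reshape(x, (n, tokens, dim))
    q = ad.reshape(_linear(ps, f"{name}.q", ad.reshape(t3, (n * tokens, dim)),
                           dim, dim), (n, tokens, dim))
    k = ad.reshape(_linear(ps, f"{name}.k", ad.reshape(t3, (n * tokens, dim)),
                           dim, dim), (n, tokens, dim))
    v = ad.reshape(_linear(ps, f"{name}.v", ad.reshape(t3, (n * tokens, dim)),
                           dim, dim), (n, tokens, dim))
    att = ad.softmax(ad.mul(ad.matmul(q, ad.transpose(k, (0, 2, 1))),
                            1.0 / np.sqrt(dim)), axis=-1)
    out = ad.matmul(att, v)
    return ad.add(x, ad.reshape(out, (n, tokens * dim)))


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

TASK_NAMES = ("dense", "named", "whr_reg", "whr_cls", "shape")


@dataclass
class TargetScaler:
    """Per-dimension standardization statistics fitted on the training set."""

    dense_mean: np.ndarray
    dense_sd: np.ndarray
    named_mean: np.ndarray
    named_sd: np.ndarray
    whr_mean: float
    whr_sd: float
    shape_mean: np.ndarray
    shape_sd: np.ndarray

    @staticmethod
    def fit(examples: list[MultiViewExample]) -> "TargetScaler":
        dense = np.stack([e.targets.dense for e in examples])
        named = np.stack([_named_vector(e) for e in examples])
        whr = np.array([e.targets.whr for e in examples])
        shape = np.stack([e.shape_vector for e in examples])

        def stats(a):
            return a.mean(axis=0), np.maximum(a.std(axis=0), 1e-6)

        dm, ds = stats(dense)
        nm, ns = stats(named)
        sm, ss = stats(shape)
        return TargetScaler(dm, ds, nm, ns, float(whr.mean()),
                            float(max(whr.std(), 1e-6)), sm, ss)


NAMED_ORDER = ("hip", "waist", "chest", "thigh", "calf", "bicep")


def _named_vector(e: MultiViewExample) -> np.ndarray:
    return np.array([e.targets.named[n] for n in NAMED_ORDER])


class MeasureNet:
    """The trainable multi-view regressor (one sex, or sex-neutral)."""

    TRUNK_DIM = 96
    TOKENS = 6

    def __init__(self, config: NetConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.ps = _ParamStore(self.rng)
        self.scaler: TargetScaler | None = None
        # calibration of the WHR classification member, fitted on the
        # training set after fitting: softmax temperature and an affine
        # debias of the expectation decode (raw decode is shrunk toward the
        # prior mean whenever the head is under-confident)
        self.cls_temperature: float = 1.0
        self.cls_affine: tuple[float, float] = (1.0, 0.0)
        w = config.width_mult
        self.widths = [int(16 * w), int(24 * w), int(32 * w), int(48 * w)]
        self._loss_theta = {
            t: Tensor(np.zeros(1, dtype=np.float64), requires_grad=True)
            for t in self._task_names()
        }
        # build parameters eagerly so num_params is meaningful pre-training
        res = config.resolution
        dummy = {v: np.zeros((1, *res), dtype=np.uint8)
                 for v in config.view_names}
        self.forward(dummy, np.zeros((1, 3), dtype=np.float32))

    def _task_names(self) -> tuple[str, ...]:
        names = list(TASK_NAMES)
        if self.config.predict_pose:
            names.append("pose")
        if self.config.predict_camera:
            names.append("camera")
        return tuple(names)

    # ---- forward ----------------------------------------------------------

    def _backbone(self, name: str, x: Tensor, record=None) -> Tensor:
        cfg = self.config
        act = cfg.activation
        c0, c1, c2, c3 = self.widths
        h = _conv(self.ps, f"{name}.stem", x, N_CLASSES, c0, 5, 2)
        if record is not None:
            record.append(h)
        h = _act(h, act)
        h = _res_conv_block(self.ps, f"{name}.b1", h, c0, c1, 2, act,
                            cfg.use_squeeze_excitation, record)
        h = _res_conv_block(self.ps, f"{name}.b2", h, c1, c2, 2, act,
                            cfg.use_squeeze_excitation, record)
        h = _res_conv_block(self.ps, f"{name}.b3", h, c2, c3, 2, act,
                            cfg.use_squeeze_excitation, record)
        return ad.global_avg_pool(h)                  # (N, c3)

    PROFILE_DIM = 48

    def _profile_branch(self, name: str, prof_px: np.ndarray,
                        extents: np.ndarray, heights_m: np.ndarray) -> Tensor:
        """Anisotropic pooling branch: per-part row-occupancy profiles.

        ``prof_px`` holds per-part-group pixel widths resampled onto a
        normalized body-height grid (computed from the *uncropped* label map,
        so no resampling quantization is added); dividing by the body's pixel
        extent and multiplying by the known height converts them to meters.
        A linear layer compresses them into the trunk. This hands the trunk
        well-conditioned width evidence that the strided convolutional path
        can only represent diffusely at desk scale.
        """
        scale = (heights_m / np.maximum(extents, 1.0)).astype(np.float32)
        flat = (prof_px * scale[:, None] * 10.0).astype(np.float32)
        z = _linear(self.ps, f"{name}.proj", Tensor(flat), flat.shape[1],
                    self.PROFILE_DIM)
        return _act(z, self.config.activation)

    def forward(self, views: dict[str, np.ndarray], scalars: np.ndarray,
                record=None, encoded: dict | None = None) -> dict[str, Tensor]:
        """views: name -> (N,H,W) uint8 label maps or (H,W) for a single
        example; scalars: (N,3) normalized [height, weight, sex].

        ``encoded`` optionally supplies pre-computed per-view encodings
        (cropped maps, profile features, extents) as cached by training."""
        cfg = self.config
        act = cfg.activation
        views = {k: (v[None] if v.ndim == 2 else v) for k, v in views.items()}
        n = next(iter(views.values())).shape[0]
        scalars = np.atleast_2d(scalars).astype(np.float32)
        heights_m = scalars[:, 0] * 0.1 + 1.7
        missing = [v for v in cfg.view_names if v not in views]
        if missing:
            raise ValueError(
                f"model configured for views {cfg.view_names} but "
                f"missing {missing}"
            )
        feats = []
        for name in cfg.view_names:
            lab = views[name]
            if lab.shape[1:] != tuple(cfg.resolution):
                raise ValueError(
                    f"view {name!r} resolution {lab.shape[1:]} does not match "
                    f"configured {tuple(cfg.resolution)}"
                )
            if encoded is not None:
                crop, prof, ext = encoded[name]
            else:
                prof_ext = [profile_features(im) for im in lab]
                prof = np.stack([p for p, _ in prof_ext])
                ext = np.array([e for _, e in prof_ext])
                crop = (np.stack([canonicalize_labels(im) for im in lab])
                        if cfg.body_centric_crop else lab)
            onehot = np.eye(N_CLASSES, dtype=np.float32)[crop]  # (N,H,W,K)
            x = Tensor(np.ascontiguousarray(onehot.transpose(0, 3, 1, 2)))
            feats.append(self._backbone(f"view_{name}", x, record))
            feats.append(self._profile_branch(f"view_{name}.profile", prof,
                                              ext, heights_m))
        feats.append(Tensor(scalars))
        h = ad.concat(feats, axis=-1)
        d_in = (self.widths[3] + self.PROFILE_DIM) * len(cfg.view_names) + 3
        h = _act(_linear(self.ps, "trunk.in", h, d_in, self.TRUNK_DIM), act)
        for i in range(4):  # residual trunk
            h = _res_fc_block(self.ps, f"trunk.res{i}", h, self.TRUNK_DIM, act,
                              record)
        if cfg.use_self_attention:
            h = _self_attention(self.ps, "attn", h, self.TOKENS,
                                self.TRUNK_DIM // self.TOKENS)
        h = _act(_linear(self.ps, "head.shared", h, self.TRUNK_DIM,
                         self.TRUNK_DIM), act)
        out = {
            "dense": _linear(self.ps, "head.dense", h, self.TRUNK_DIM, 112),
            "named": _linear(self.ps, "head.named", h, self.TRUNK_DIM, 6),
            "whr_reg": _linear(self.ps, "head.whr_reg", h, self.TRUNK_DIM, 1),
            "whr_cls": _linear(self.ps, "head.whr_cls", h, self.TRUNK_DIM,
                               self.config.whr_bins[2]),
            "shape": _linear(self.ps, "head.shape", h, self.TRUNK_DIM, 9),
        }
        if cfg.predict_pose:
            out["pose"] = _linear(self.ps, "head.pose", h, self.TRUNK_DIM, 1)
        if cfg.predict_camera:
            out["camera"] = _linear(self.ps, "head.camera", h, self.TRUNK_DIM, 6)
        return out

    # ---- parameters -------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.ps.params.values()) + list(self._loss_theta.values())

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.ps.params.values()))

    def loss_weights(self) -> dict[str, float]:
        return {t: float(np.logaddexp(0.0, th.data[0]))
                for t, th in self._loss_theta.items()}

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {f"param:{k}": v.data for k, v in self.ps.params.items()}
        d |= {f"theta:{k}": v.data for k, v in self._loss_theta.items()}
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k, v in d.items():
            kind, name = k.split(":", 1)
            store = self.ps.params if kind == "param" else self._loss_theta
            store[name].data = np.array(v)


# ---------------------------------------------------------------------------
# Uncertainty-weighted multi-task loss
# ---------------------------------------------------------------------------

def multitask_loss(task_losses: dict, weight_theta: dict
                   ) -> tuple[Tensor, dict[str, float]]:
    """Total loss  sum_i [ L_i / w_i + log(1 + w_i) ]  with w_i = softplus(theta_i).

    ``task_losses`` maps task name -> scalar Tensor (or float); ``weight_theta``
    maps task name -> unconstrained Tensor parameter. Gradients flow to both
    the task losses and the weights. Raises on non-finite task losses.
    """
    total = None
    breakdown: dict[str, float] = {}
    for name, li in task_losses.items():
        li_t = li if isinstance(li, Tensor) else Tensor(np.asarray(float(li)))
        val = float(np.asarray(li_t.data).reshape(-1)[0])
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss for task {name!r}: {val}")
        w = ad.softplus(weight_theta[name])
        term = ad.add(ad.mul(li_t, ad.power(w, -1.0)), ad.log1p(w))
        term = ad.reduce_sum(term)
        breakdown[name] = val
        total = term if total is None else ad.add(total, term)
    return total, breakdown


def ensemble_whr(pred: Prediction, bin_centers: np.ndarray,
                 cls_affine: tuple[float, float] = (1.0, 0.0)) -> float:
    """Average of the WHR members: regression head, classification-head
    expectation (optionally affine-debiased with train-fitted coefficients),
    and the named waist/hip ratio. A non-positive predicted hip drops the
    ratio member with a warning."""
    gain, offset = cls_affine
    members = [pred.whr_regression,
               gain * float(np.dot(pred.whr_class_probabilities, bin_centers))
               + offset]
    hip = pred.named.get("hip", 0.0)
    waist = pred.named.get("waist", 0.0)
    if hip > 0:
        members.append(waist / hip)
    else:
        warnings.warn("predicted hip <= 0; WHR ensemble drops the ratio member",
                      stacklevel=2)
    return float(np.mean(members))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled weight decay on matrix/kernel parameters."""

    def __init__(self, params: list[Tensor], lr: float,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + eps)
            if self.weight_decay and p.data.ndim >= 2:
                p.data = p.data - self.lr * self.weight_decay * p.data


def _soft_bin(whr: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Linear soft assignment of each WHR to the two nearest bin centers."""
    centers = np.linspace(lo, hi, n + 1)
    centers = 0.5 * (centers[:-1] + centers[1:])
    width = centers[1] - centers[0]
    out = np.zeros((len(whr), n))
    pos = np.clip((whr - centers[0]) / width, 0.0, n - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    f = pos - i0
    out[np.arange(len(whr)), i0] += 1.0 - f
    out[np.arange(len(whr)), i1] += f
    return out


PROFILE_GROUP_NAMES = ("torso", "left_leg", "right_leg", "left_arm",
                       "right_arm")
PROFILE_ROWS = 40


def profile_features(lab: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-part-group row-occupancy widths on a normalized body-height grid.

    Computed on the raw label map (no resampling of labels, so no added
    quantization); returns (features (groups*rows,), body pixel extent).
    """
    from .parts import PART_GROUPS

    h = lab.shape[0]
    occ = lab.any(axis=1)
    rows = np.nonzero(occ)[0]
    if len(rows) == 0:
        return np.zeros(len(PROFILE_GROUP_NAMES) * PROFILE_ROWS,
                        dtype=np.float32), 1.0
    top, bot = int(rows[0]), int(rows[-1])
    extent = float(max(bot - top, 1))
    grid = np.linspace(top, bot, PROFILE_ROWS)
    feats = []
    for g in PROFILE_GROUP_NAMES:
        m = np.isin(lab, tuple(PART_GROUPS[g])).sum(axis=1).astype(float)
        feats.append(np.interp(grid, np.arange(h), m))
    return np.concatenate(feats).astype(np.float32), extent


def canonicalize_labels(lab: np.ndarray, margin: int = 1) -> np.ndarray:
    """Body-centric crop: rescale the label map isotropically so the body's
    vertical extent fills the frame, centered horizontally.

    This removes the camera's distance/focal scale ambiguity (physical widths
    become pixel widths times subject height over frame height) and uses the
    full input resolution on the body. Nearest-neighbor lookup keeps labels
    categorical; blank images pass through unchanged.
    """
    h, w = lab.shape
    rows = np.nonzero(lab.any(axis=1))[0]
    if len(rows) == 0:
        return lab
    cols = np.nonzero(lab.any(axis=0))[0]
    top, bot = int(rows[0]), int(rows[-1])
    cx = 0.5 * (cols[0] + cols[-1])
    extent = max(bot - top + 1, 1)
    scale = (h - 2 * margin) / extent
    yy = top + (np.arange(h) - margin) / scale
    xx = cx + (np.arange(w) - (w - 1) / 2) / scale
    yi = np.clip(np.round(yy), 0, h - 1).astype(np.int64)
    xi = np.clip(np.round(xx), 0, w - 1).astype(np.int64)
    out = lab[yi][:, xi].copy()
    out[(yy < -0.5) | (yy > h - 0.5)] = 0
    out[:, (xx < -0.5) | (xx > w - 0.5)] = 0
    return out


SEX_CODE = {"male": 1.0, "female": -1.0}


def encode_scalars(examples: list[MultiViewExample]) -> np.ndarray:
    h = np.array([e.height for e in examples])
    w = np.array([e.weight for e in examples])
    s = np.array([SEX_CODE[e.sex] for e in examples])
    return np.stack([(h - 1.7) / 0.1, (w - 80.0) / 15.0, s], axis=1
                    ).astype(np.float32)


def _batch_views(examples: list[MultiViewExample],
                 view_names: tuple[str, ...]) -> dict[str, np.ndarray]:
    return {v: np.stack([e.images[v].data for e in examples])
            for v in view_names}


def _batch_loss(model: MeasureNet, batch: list[MultiViewExample],
                scaler: TargetScaler,
                encoded: dict | None = None) -> tuple[Tensor, dict[str, float]]:
    cfg = model.config
    views = _batch_views(batch, cfg.view_names)
    scalars = encode_scalars(batch)
    out = model.forward(views, scalars, encoded=encoded)

    dense_t = (np.stack([e.targets.dense for e in batch]) - scaler.dense_mean
               ) / scaler.dense_sd
    named_t = (np.stack([_named_vector(e) for e in batch]) - scaler.named_mean
               ) / scaler.named_sd
    whr = np.array([e.targets.whr for e in batch])
    whr_t = (whr - scaler.whr_mean) / scaler.whr_sd
    shape_t = (np.stack([e.shape_vector for e in batch]) - scaler.shape_mean
               ) / scaler.shape_sd
    lo, hi, nb = cfg.whr_bins
    cls_t = _soft_bin(whr, lo, hi, nb)

    mse = lambda y, t: ad.reduce_mean(ad.power(y - Tensor(t.astype(np.float32)),
                                               2.0))
    losses = {
        "dense": mse(out["dense"], dense_t),
        "named": mse(out["named"], named_t),
        "whr_reg": mse(ad.reshape(out["whr_reg"], (len(batch),)), whr_t),
        "whr_cls": ad.cross_entropy(out["whr_cls"], cls_t),
        "shape": mse(out["shape"], shape_t),
    }
    if cfg.predict_pose:
        pose_t = np.array([[e.params.shoulder_abduction_deg / 20.0 - 1.0]
                           for e in batch])
        losses["pose"] = mse(out["pose"], pose_t)
    if cfg.predict_camera:
        cam_t = np.stack([
            np.concatenate([
                [np.linalg.norm(e.cameras[v].position) / 2.7 - 1.0,
                 e.cameras[v].position[1] / 1.2 - 1.0]
                for v in ("front", "side", "back")])
            for e in batch])
        losses["camera"] = mse(out["camera"], cam_t)
    return multitask_loss(losses, model._loss_theta)


def train_model(dataset: list[MultiViewExample], config: NetConfig
                ) -> tuple[MeasureNet, pd.DataFrame]:
    """Train on multi-view examples; returns (model, per-epoch history).

    Training is deterministic given the config seed (pure numpy backend).
    On divergence (non-finite loss) training aborts and the parameters from
    the end of the last completed epoch are restored.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    for e in dataset:
        if e.targets.dense is None:
            raise ValueError("dataset examples must carry dense ring targets")
    model = MeasureNet(config)
    scaler = TargetScaler.fit(dataset)
    model.scaler = scaler
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    checkpoint = model.state_dict()
    checkpoint = {k: v.copy() for k, v in checkpoint.items()}
    # encode every view once up front (body-centric crop + profile features)
    all_enc: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for v in config.view_names:
        imgs = np.stack([e.images[v].data for e in dataset])
        prof_ext = [profile_features(im) for im in imgs]
        prof = np.stack([p for p, _ in prof_ext])
        ext = np.array([e for _, e in prof_ext])
        crop = (np.stack([canonicalize_labels(im) for im in imgs])
                if config.body_centric_crop else imgs)
        all_enc[v] = (crop, prof, ext)
    try:
        for epoch in range(config.epochs):
            # cosine decay to 10% of the base rate over the epoch budget
            frac = epoch / max(config.epochs - 1, 1)
            opt.lr = config.lr * (0.1 + 0.45 * (1.0 + np.cos(np.pi * frac)))
            order = rng.permutation(len(dataset))
            totals: dict[str, float] = {}
            nb = 0
            for start in range(0, len(dataset), config.batch_size):
                idx = order[start:start + config.batch_size]
                batch = [dataset[i] for i in idx]
                enc = {v: (c[idx], p[idx], e[idx])
                       for v, (c, p, e) in all_enc.items()}
                opt.zero_grad()
                total, breakdown = _batch_loss(model, batch, scaler,
                                               encoded=enc)
                total.backward()
                opt.step()
                for k, v in breakdown.items():
                    totals[k] = totals.get(k, 0.0) + v
                totals["total"] = totals.get("total", 0.0) + float(total.data)
                nb += 1
            row = {"epoch": epoch} | {k: v / nb for k, v in totals.items()}
            row |= {f"w_{k}": v for k, v in model.loss_weights().items()}
            history.append(row)
            checkpoint = {k: v.copy() for k, v in model.state_dict().items()}
    except FloatingPointError:
        model.load_state_dict(checkpoint)
        raise
    _calibrate_cls_temperature(model, dataset, all_enc)
    return model, pd.DataFrame(history)


def _calibrate_cls_temperature(model: MeasureNet,
                               dataset: list[MultiViewExample],
                               all_enc: dict) -> None:
    """Temperature-scale the WHR classification head on the training set.

    A freshly trained head is typically under-confident at desk scale; its
    expectation decode is then shrunk toward the prior mean, which biases the
    classification member of the WHR ensemble and understates its true
    repeatability spread. Standard temperature scaling (one scalar fitted by
    minimizing the soft-binned cross-entropy on the training data) restores
    calibrated probabilities; no held-out information is used.
    """
    from scipy.optimize import minimize_scalar

    cfg = model.config
    lo, hi, nb = cfg.whr_bins
    whr = np.array([e.targets.whr for e in dataset])
    targets = _soft_bin(whr, lo, hi, nb)
    logits = []
    for start in range(0, len(dataset), 64):
        idx = np.arange(start, min(start + 64, len(dataset)))
        batch = [dataset[i] for i in idx]
        enc = {v: (c[idx], p[idx], e[idx]) for v, (c, p, e) in all_enc.items()}
        out = model.forward(_batch_views(batch, cfg.view_names),
                            encode_scalars(batch), encoded=enc)
        logits.append(out["whr_cls"].data)
    z = np.vstack(logits)

    def nll(log_t: float) -> float:
        zz = z / np.exp(log_t)
        zz = zz - zz.max(axis=1, keepdims=True)
        logp = zz - np.log(np.exp(zz).sum(axis=1, keepdims=True))
        return float(-(targets * logp).sum(axis=1).mean())

    res = minimize_scalar(nll, bounds=(np.log(0.05), np.log(20.0)),
                          method="bounded")
    model.cls_temperature = float(np.exp(res.x))

    # affine debias of the expectation decode: the conditional-mean decode of
    # an under-confident head is shrunk toward the prior mean, which would
    # bias the ensemble; fit whr ~ a*decode + b on the training set
    zz = z / model.cls_temperature
    zz = zz - zz.max(axis=1, keepdims=True)
    p = np.exp(zz)
    p /= p.sum(axis=1, keepdims=True)
    centers = cfg.bin_centers()
    e = p @ centers
    a_mat = np.stack([e, np.ones_like(e)], axis=1)
    coef, *_ = np.linalg.lstsq(a_mat, whr, rcond=None)
    gain = float(np.clip(coef[0], 0.2, 25.0))
    model.cls_affine = (gain, float(coef[1]) if gain == coef[0]
                        else float(whr.mean() - gain * e.mean()))


def train_sex_specific(datasets: dict[str, list[MultiViewExample]],
                       config: NetConfig
                       ) -> dict[str, tuple[MeasureNet, pd.DataFrame]]:
    """Train one model per sex; examples are routed by their sex at predict time."""
    return {sex: train_model(data, config) for sex, data in datasets.items()}


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _raw_predict(model: MeasureNet, example: MultiViewExample) -> Prediction:
    cfg = model.config
    sc = model.scaler
    if sc is None:
        raise RuntimeError("model has no fitted target scaler (untrained?)")
    views = {v: example.images[v].data for v in cfg.view_names
             if v in example.images}
    out = model.forward(views, encode_scalars([example]))
    dense = out["dense"].data[0] * sc.dense_sd + sc.dense_mean
    named_v = out["named"].data[0] * sc.named_sd + sc.named_mean
    named = dict(zip(NAMED_ORDER, map(float, named_v)))
    whr_reg = float(out["whr_reg"].data[0, 0] * sc.whr_sd + sc.whr_mean)
    z = out["whr_cls"].data[0] / model.cls_temperature
    z = z - z.max()
    probs = np.exp(z) / np.exp(z).sum()
    shape = out["shape"].data[0] * sc.shape_sd + sc.shape_mean
    return Prediction(dense=dense, named=named, whr_regression=whr_reg,
                      whr_class_probabilities=probs, shape_estimate=shape)


def predict(model: MeasureNet, example: MultiViewExample):
    """Predict named circumferences (mm) and ensemble WHR for one example.

    In 'direct' mode circumferences come straight from the regression heads.
    In 'shape-decode' mode the predicted shape vector is decoded to a mesh and
    tape-measured (the reconstruct-then-measure baseline).
    """
    from .tape_measure import MeasurementSet

    pred = _raw_predict(model, example)
    cfg = model.config
    if cfg.mode == "shape-decode":
        from .body_model import BodyShapeParams, build_mesh
        from .tape_measure import named_measurements

        params = BodyShapeParams.from_vector(pred.shape_estimate, example.sex,
                                             example.height)
        ms = named_measurements(build_mesh(params, angular_resolution=32))
        pred.named = dict(ms.named)
    pred.whr_final = ensemble_whr(pred, cfg.bin_centers(),
                                  cls_affine=model.cls_affine)
    named = dict(pred.named)
    whr = pred.whr_final
    return MeasurementSet(named=named, whr=whr, dense=pred.dense), pred


def whr_members(model: MeasureNet, pred: Prediction) -> dict[str, float]:
    """The individual WHR ensemble members for one prediction (the
    classification member with the model's train-fitted calibration)."""
    gain, offset = model.cls_affine
    centers = model.config.bin_centers()
    members = {
        "regression": pred.whr_regression,
        "classification": gain * float(pred.whr_class_probabilities @ centers)
        + offset,
    }
    if pred.named.get("hip", 0.0) > 0:
        members["ratio"] = pred.named["waist"] / pred.named["hip"]
    return members


def predict_routed(models: dict[str, MeasureNet], example: MultiViewExample):
    """Route an example to the model matching its sex."""
    if example.sex not in models:
        raise KeyError(f"no model for sex {example.sex!r}")
    return predict(models[example.sex], example)


def dead_unit_fraction(model: MeasureNet, example: MultiViewExample) -> float:
    """Fraction of hidden pre-activation units with exactly zero local
    gradient for one input: ~0.5 for ReLU at initialization, 0 for Swish."""
    record: list[Tensor] = []
    views = {v: example.images[v].data for v in model.config.view_names}
    model.forward(views, encode_scalars([example]), record=record)
    dead = 0
    total = 0
    for t in record:
        x = t.data
        if model.config.activation == "relu":
            d = (x <= 0)
        else:
            s = 1.0 / (1.0 + np.exp(-x))
            d = np.abs(s + x * s * (1 - s)) < 1e-12
        dead += int(d.sum())
        total += d.size
    return dead / max(total, 1)
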