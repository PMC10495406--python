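"""Procedural parametric human body model and population sampling.

The body is a stack of generalized cylinders (elliptical cross-sections with
smoothly interpolated semi-axes) plus an ellipsoidal head: an analytic,
license-free parameterization in which every named circumference (hip, waist,
chest, thigh, calf, bicep) is directly controllable and recoverable by the
virtual tape measure to within discretization error.

Cohort generation follows a three-step pipeline: sample a bootstrap
measurement table from a scan-population spec, fit a sex-specific Gaussian
mixture (component count chosen by BIC), then importance-sample the mixture
toward a target population spec so the synthetic cohort's marginals match the
target distribution.

Units: geometry and heights in meters (canonical frame: y up, x left-right,
z front-back, feet at y = 0); circumferences in millimeters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import lognorm, norm
from sklearn.mixture import GaussianMixture

from .parts import PART_IDS

MEASUREMENT_NAMES = ["hip", "waist", "chest", "thigh", "calf", "bicep"]
FEATURE_COLUMNS = ["height", "weight"] + MEASUREMENT_NAMES

BODY_DENSITY_KG_M3 = 985.0  # whole-body average, used to derive weight from mesh volume

# Longitudinal landmark stations, normalized 0 (floor) to 1 (crown).
DEFAULT_STATIONS = {
    "calf": 0.18,
    "thigh": 0.46,
    "hip": 0.53,
    "waist": 0.63,
    "chest": 0.72,
}
BICEP_ARM_FRACTION = 0.22  # along the arm axis, 0 = shoulder


# ---------------------------------------------------------------------------
# Population specification and measurement tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marginal:
    """One marginal distribution: 'normal' or 'lognormal', moment-matched."""

    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not (self.mean > 0 and self.sd > 0):
            raise ValueError("marginal mean and sd must be strictly positive")

    def _lognorm_params(self) -> tuple[float, float]:
        # moment matching: mean/sd of the lognormal itself, not of log(X)
        s2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - 0.5 * s2
        return mu, math.sqrt(s2)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            return norm.ppf(q, loc=self.mean, scale=self.sd)
        mu, sig = self._lognorm_params()
        return lognorm.ppf(q, sig, scale=math.exp(mu))

    def pdf(self, x: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            return norm.pdf(x, loc=self.mean, scale=self.sd)
        mu, sig = self._lognorm_params()
        return lognorm.pdf(x, sig, scale=math.exp(mu))


@dataclass(frozen=True)
class PopulationSpec:
    """Sex-specific anthropometric population: marginals + a Gaussian copula.

    ``correlation`` is the equicorrelation of the latent Gaussian copula among
    weight and the six circumferences (a shared "size" factor);
    ``height_correlation`` couples height to that factor more weakly.
    ``aspect_mean``/``aspect_sd`` control the per-subject depth/width ratio of
    elliptical cross-sections, the main source of genuinely 3D shape variation
    that a single front view cannot resolve.
    """

    sex: str
    marginals: dict[str, Marginal]
    correlation: float = 0.55
    height_correlation: float = 0.30
    aspect_mean: float = 0.75
    aspect_sd: float = 0.04
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        missing = [c for c in FEATURE_COLUMNS if c not in self.marginals]
        if missing:
            raise ValueError(f"missing marginals for {missing}")
        for name, m in self.marginals.items():
            lo, hi = self.bounds.get(name, (0.0, np.inf))
            if not (lo <= m.mean <= hi):
                raise ValueError(
                    f"{name} mean {m.mean} outside physiological bounds [{lo}, {hi}]"
                )
        whr = self.marginals["waist"].mean / self.marginals["hip"].mean
        if not (0.6 <= whr <= 1.2):
            raise ValueError(f"implied mean WHR {whr:.3f} outside [0.6, 1.2]")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")

    @property
    def mean_whr(self) -> float:
        return self.marginals["waist"].mean / self.marginals["hip"].mean

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw n subjects via the Gaussian copula; returns a MeasurementTable."""
        if n < 1:
            raise ValueError("n must be >= 1")
        f = rng.standard_normal(n)  # shared size factor
        cols = {}
        for name in FEATURE_COLUMNS:
            rho = self.height_correlation if name == "height" else self.correlation
            z = math.sqrt(rho) * f + math.sqrt(1.0 - rho) * rng.standard_normal(n)
            q = norm.cdf(z)
            cols[name] = self.marginals[name].ppf(q)
        df = pd.DataFrame(cols)
        df.insert(0, "sex", self.sex)
        df.insert(0, "subject_id", np.arange(n))
        return df

    def marginal_pdf(self, x: np.ndarray) -> np.ndarray:
        """Product-of-marginals density over FEATURE_COLUMNS (target for IS)."""
        x = np.asarray(x, dtype=float)
        p = np.ones(x.shape[0])
        for j, name in enumerate(FEATURE_COLUMNS):
            p *= self.marginals[name].pdf(x[:, j])
        return p


DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "height": (1.2, 2.2),
    "weight": (30.0, 250.0),
    "hip": (600.0, 1800.0),
    "waist": (500.0, 1500.0),
    "chest": (600.0, 1800.0),
    "thigh": (300.0, 1100.0),
    "calf": (200.0, 700.0),
    "bicep": (150.0, 600.0),
}


def default_population(sex: str) -> PopulationSpec:
    """Default North-American-like marginals; mean WHR 0.90 (male) / 0.85 (female)."""
    if sex == "male":
        m = {
            "height": Marginal("normal", 1.755, 0.072),
            "weight": Marginal("lognormal", 85.0, 14.0),
            "hip": Marginal("lognormal", 1020.0, 80.0),
            "waist": Marginal("lognormal", 918.0, 110.0),
            "chest": Marginal("lognormal", 1040.0, 90.0),
            "thigh": Marginal("lognormal", 580.0, 55.0),
            "calf": Marginal("lognormal", 385.0, 30.0),
            "bicep": Marginal("lognormal", 330.0, 40.0),
        }
    elif sex == "female":
        m = {
            "height": Marginal("normal", 1.618, 0.065),
            "weight": Marginal("lognormal", 72.0, 13.0),
            "hip": Marginal("lognormal", 1040.0, 85.0),
            "waist": Marginal("lognormal", 884.0, 105.0),
            "chest": Marginal("lognormal", 980.0, 85.0),
            "thigh": Marginal("lognormal", 585.0, 55.0),
            "calf": Marginal("lognormal", 370.0, 28.0),
            "bicep": Marginal("lognormal", 300.0, 38.0),
        }
    else:
        raise ValueError("sex must be 'male' or 'female'")
    return PopulationSpec(sex=sex, marginals=m)


def scan_population(sex: str) -> PopulationSpec:
    """Bootstrap 'scan' population: like the target but mildly biased.

    Stands in for the distribution of an opportunistically collected laser-scan
    library, which importance sampling then corrects toward the target.
    """
    target = default_population(sex)
    shifted = dict(target.marginals)
    shifted["waist"] = replace(shifted["waist"], mean=shifted["waist"].mean * 1.05)
    shifted["hip"] = replace(shifted["hip"], mean=shifted["hip"].mean * 0.98)
    return replace(target, marginals=shifted)


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in ["subject_id", "sex"] + FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    if table[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("measurement table contains missing values")
    if (table[MEASUREMENT_NAMES] <= 0).any().any():
        raise ValueError("circumferences must be strictly positive")
    if table["subject_id"].duplicated().any():
        raise ValueError("one row per subject required (duplicate subject_id)")


# ---------------------------------------------------------------------------
# Mixture fitting and importance sampling
# ---------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """A fitted sex-specific Gaussian mixture over the measurement space."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    bic_by_k: dict[int, float]
    feature_names: list[str]
    _gmm: GaussianMixture

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        return self._gmm.score_samples(np.asarray(x, dtype=float))

    def sample(self, n: int, seed: int) -> np.ndarray:
        self._gmm.random_state = seed  # sklearn's sample() uses this state
        x, _ = self._gmm.sample(n)
        return x


def fit_population_model(
    table: pd.DataFrame,
    max_clusters: int = 8,
    seed: int = 0,
    covariance_type: str = "full",
) -> MixtureModel:
    """Fit Gaussian mixtures for k = 1..max_clusters and keep the BIC minimizer.

    A covariance floor (reg_covar = 1e-6) guards against degenerate clusters;
    if the data itself is (near) singular a warning is logged and the floored
    fit is returned.
    """
    validate_table(table)
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    n = len(table)
    if n < 10 * max_clusters:
        raise ValueError(
            f"need at least {10 * max_clusters} rows to consider up to "
            f"{max_clusters} clusters, got {n}"
        )
    x = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.cov(x.T) + 0.0) < x.shape[1]:
        warnings.warn(
            "near-singular sample covariance; applying covariance floor", stacklevel=2
        )
    bic_by_k: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, max_clusters + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            reg_covar=1e-6,
            n_init=3,
            random_state=seed,
        )
        gmm.fit(x)
        bic_by_k[k] = float(gmm.bic(x))
        fits[k] = gmm
    best_k = min(bic_by_k, key=bic_by_k.get)
    best = fits[best_k]
    cov = best.covariances_
    if covariance_type == "diag":
        cov = np.stack([np.diag(c) for c in cov])
    return MixtureModel(
        n_components=best_k,
        weights=best.weights_.copy(),
        means=best.means_.copy(),
        covariances=cov.copy(),
        bic_by_k=bic_by_k,
        feature_names=list(FEATURE_COLUMNS),
        _gmm=best,
    )


def importance_sample(
    model: MixtureModel,
    target: PopulationSpec,
    n: int,
    seed: int = 0,
    proposal_factor: int = 8,
) -> np.ndarray:
    """Self-normalized importance resampling of the mixture toward the target.

    Draws ``proposal_factor * n`` proposals from the mixture, weights each by
    target density (product of the target marginals) over mixture density, and
    resamples ``n`` vectors with replacement proportionally to the weights.
    Returns an (n, 8) array over FEATURE_COLUMNS.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # a floor on the proposal pool keeps the effective sample size meaningful
    # even for small requested cohorts
    m = max(proposal_factor * n, 5000)
    pool = model.sample(m, seed=seed)
    pool = np.maximum(pool, 1e-6)  # mixture tails can graze zero
    log_q = model.log_pdf(pool)
    with np.errstate(divide="ignore"):
        log_p = np.log(target.marginal_pdf(pool))
    log_w = log_p - log_q

    def _degenerate(ess: float) -> ValueError:
        # name the marginal where model and target disagree the most
        shifts = {}
        for j, name in enumerate(FEATURE_COLUMNS):
            tm = target.marginals[name]
            shifts[name] = abs(pool[:, j].mean() - tm.mean) / tm.sd
        worst = max(shifts, key=shifts.get)
        return ValueError(
            f"degenerate importance weights (effective sample size {ess:.1f} "
            f"< 10); largest marginal mismatch on {worst!r} "
            f"({shifts[worst]:.1f} target sds)"
        )

    finite = np.isfinite(log_w)
    if not np.any(finite):
        raise _degenerate(0.0)
    log_w = log_w - log_w[finite].max()
    w = np.where(finite, np.exp(np.where(finite, log_w, -np.inf)), 0.0)
    w /= w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < 10.0:
        raise _degenerate(ess)
    idx = rng.choice(m, size=n, replace=True, p=w)
    return pool[idx]


# ---------------------------------------------------------------------------
# Shape parameters
# ---------------------------------------------------------------------------

def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the perimeter of an ellipse."""
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def semi_axis_from_circumference(c_mm: float, aspect: float) -> float:
    """Invert Ramanujan's formula for the major semi-axis a with b = aspect*a."""
    factor = math.pi * (
        3.0 * (1.0 + aspect) - math.sqrt((3.0 + aspect) * (1.0 + 3.0 * aspect))
    )
    return (c_mm / 1000.0) / factor


@dataclass(frozen=True)
class BodyShapeParams:
    """Low-dimensional description of one synthetic body.

    ``semi_axes`` holds the width (x) semi-axis at each named landmark station
    in meters; ``aspects`` the depth/width ratio per body part. Landmark
    stations are normalized floor-to-crown heights (bicep lives on the arm's
    own axis as a 0-1 fraction from the shoulder).
    """

    sex: str
    height: float
    semi_axes: dict[str, float]
    aspects: dict[str, float]
    stations: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATIONS))
    bicep_fraction: float = BICEP_ARM_FRACTION
    shoulder_abduction_deg: float = 20.0
    hip_abduction_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (1.2 <= self.height <= 2.2):
            raise ValueError(f"height {self.height} m outside [1.2, 2.2]")
        for k, v in self.semi_axes.items():
            if v <= 0:
                raise ValueError(f"semi-axis {k} must be > 0")
        s = self.stations
        if not (s["calf"] < s["thigh"] < s["hip"] < s["waist"] < s["chest"]):
            raise ValueError("landmark stations must be ordered calf<thigh<hip<waist<chest")

    def as_vector(self) -> np.ndarray:
        """Flat shape vector used as a network regression target."""
        ax = [self.semi_axes[n] for n in MEASUREMENT_NAMES]
        rho = [self.aspects[p] for p in ("torso", "leg", "arm")]
        return np.array(ax + rho, dtype=float)

    @staticmethod
    def from_vector(v: np.ndarray, sex: str, height: float) -> "BodyShapeParams":
        v = np.asarray(v, dtype=float)
        semi = {n: max(float(v[i]), 1e-3) for i, n in enumerate(MEASUREMENT_NAMES)}
        asp = {
            "torso": float(np.clip(v[6], 0.4, 1.3)),
            "leg": float(np.clip(v[7], 0.4, 1.3)),
            "arm": float(np.clip(v[8], 0.4, 1.3)),
            "neck": 0.85,
            "head": 1.2,
        }
        return BodyShapeParams(sex=sex, height=height, semi_axes=semi, aspects=asp)


def shape_from_measurements(
    m,
    sex: str,
    height: float,
    aspects: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> BodyShapeParams:
    """Invert named circumferences to generalized-cylinder semi-axes.

    ``m`` maps measurement name -> circumference in mm (or is a vector over
    MEASUREMENT_NAMES). The inversion is the closed-form Ramanujan ellipse
    relation at a fixed per-part depth/width aspect ratio.
    """
    if not isinstance(m, dict):
        m = {name: float(v) for name, v in zip(MEASUREMENT_NAMES, m)}
    bounds = bounds or DEFAULT_BOUNDS
    violations = []
    for name in MEASUREMENT_NAMES:
        if name not in m:
            violations.append(f"{name}: missing")
            continue
        lo, hi = bounds[name]
        if not (lo <= m[name] <= hi):
            violations.append(f"{name}: {m[name]:.0f} mm outside [{lo:.0f}, {hi:.0f}]")
    lo, hi = bounds["height"]
    if not (lo <= height <= hi):
        violations.append(f"height: {height} m outside [{lo}, {hi}]")
    if violations:
        raise ValueError("measurements out of bounds: " + "; ".join(violations))
    aspects = dict(aspects or {})
    aspects.setdefault("torso", 0.75)
    aspects.setdefault("leg", 0.75)
    aspects.setdefault("arm", 0.75)
    aspects.setdefault("neck", 0.85)
    aspects.setdefault("head", 1.2)
    part_of = {
        "hip": "torso", "waist": "torso", "chest": "torso",
        "thigh": "leg", "calf": "leg", "bicep": "arm",
    }
    semi = {
        name: semi_axis_from_circumference(m[name], aspects[part_of[name]])
        for name in MEASUREMENT_NAMES
    }
    return BodyShapeParams(sex=sex, height=height, semi_axes=semi, aspects=aspects)


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landmark:
    """A measurement plane: origin + normal, restricted to one label group."""

    origin: np.ndarray
    normal: np.ndarray
    part_group: str


@dataclass
class BodyMesh:
    """Triangulated, part-labeled body surface with named measurement planes.

    Closed per connected component (torso, neck, head, two arms, two legs are
    separate interpenetrating closed solids). ``points`` carries auxiliary
    anatomical points (crown, knees) used by camera validity checks.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray
    landmarks: dict[str, Landmark]
    points: dict[str, np.ndarray]
    height: float

    def to_trimesh(self, faces_mask: np.ndarray | None = None):
        import trimesh

        f = self.faces if faces_mask is None else self.faces[faces_mask]
        return trimesh.Trimesh(vertices=self.vertices, faces=f, process=False)

    def volume(self) -> float:
        """Total enclosed volume (m^3), summed over closed components."""
        tm = self.to_trimesh()
        return float(sum(abs(c.volume) for c in tm.split(only_watertight=False)))

    def weight_kg(self) -> float:
        return self.volume() * BODY_DENSITY_KG_M3

    def transform(self, matrix: np.ndarray) -> "BodyMesh":
        """Apply a 4x4 rigid transform to geometry, landmarks and points."""
        r, t = matrix[:3, :3], matrix[:3, 3]
        lms = {
            k: Landmark(r @ v.origin + t, r @ v.normal, v.part_group)
            for k, v in self.landmarks.items()
        }
        pts = {k: r @ v + t for k, v in self.points.items()}
        return BodyMesh(
            vertices=self.vertices @ r.T + t,
            faces=self.faces.copy(),
            face_labels=self.face_labels.copy(),
            landmarks=lms,
            points=pts,
            height=self.height,
        )


def _tube(
    origin: np.ndarray,
    axis: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    t: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    centers: np.ndarray,
    n_theta: int,
    label_fn,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Capped generalized cylinder along ``axis``; returns (verts, faces, labels)."""
    s = len(t)
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    ct, st = np.cos(theta), np.sin(theta)
    verts = (
        origin[None, None, :]
        + axis[None, None, :] * t[:, None, None]
        + u[None, None, :] * (centers[:, 0, None] + a[:, None] * ct[None, :])[..., None]
        + v[None, None, :] * (centers[:, 1, None] + b[:, None] * st[None, :])[..., None]
    ).reshape(s * n_theta, 3)
    faces, labels = [], []
    for i in range(s - 1):
        lab = label_fn(0.5 * (t[i] + t[i + 1]))
        r0, r1 = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append((r0 + j, r0 + jn, r1 + j))
            faces.append((r0 + jn, r1 + jn, r1 + j))
            labels.extend((lab, lab))
    # end caps: fan around ring centroid
    cap0 = origin + axis * t[0] + u * centers[0, 0] + v * centers[0, 1]
    cap1 = origin + axis * t[-1] + u * centers[-1, 0] + v * centers[-1, 1]
    verts = np.vstack([verts, cap0, cap1])
    i0, i1 = s * n_theta, s * n_theta + 1
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append((i0, (j + 1) % n_theta, j))
        labels.append(label_fn(t[0]))
        top = (s - 1) * n_theta
        faces.append((i1, top + j, top + jn))
        labels.append(label_fn(t[-1]))
    return verts, np.array(faces, dtype=np.int64), np.array(labels, dtype=np.int16)


def _profile(stations: np.ndarray, values: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Monotone-cubic profile through control points, clamped outside."""
    interp = PchipInterpolator(stations, values, extrapolate=False)
    out = interp(np.clip(query, stations[0], stations[-1]))
    return np.asarray(out)


def _stations_with(lo: float, hi: float, n: int, required: list[float]) -> np.ndarray:
    """Evenly spaced stations on [lo, hi] with required stations inserted exactly."""
    base = np.linspace(lo, hi, n)
    req = [x for x in required if lo < x < hi]
    t = np.unique(np.concatenate([base, np.array(req)]))
    # drop base stations that collide with a required one to keep spacing sane
    keep = np.ones(len(t), dtype=bool)
    for x in req:
        close = np.abs(t - x) < (hi - lo) / (4 * n)
        close[np.argmin(np.abs(t - x))] = False
        keep &= ~close
    return t[keep]


def build_mesh(
    params: BodyShapeParams,
    angular_resolution: int = 48,
    stations: int = 40,
) -> BodyMesh:
    """Build the labeled triangle mesh realizing ``params``.

    ``stations`` is the longitudinal resolution of the torso; limbs use a
    proportional count. Landmark stations are inserted exactly so that the
    tape measure recovers requested circumferences up to the polygonal
    approximation of the ellipse (< 0.2% at 48 segments).
    """
    if angular_resolution < 16:
        raise ValueError("angular_resolution must be >= 16")
    if stations < 20:
        raise ValueError("stations must be >= 20")
    H = params.height
    st = params.stations
    sa = params.semi_axes
    rho_t = params.aspects["torso"]
    rho_l = params.aspects["leg"]
    rho_a = params.aspects["arm"]

    ey = np.array([0.0, 1.0, 0.0])
    ex = np.array([1.0, 0.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    zero2 = lambda n: np.zeros((n, 2))

    parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    # --- torso -------------------------------------------------------------
    y_hip, y_waist, y_chest = st["hip"] * H, st["waist"] * H, st["chest"] * H
    y_bot, y_top = 0.50 * H, 0.855 * H
    ctrl_y = np.array([y_bot, y_hip, y_waist, y_chest, 0.80 * H, y_top])
    ctrl_a = np.array(
        [0.97 * sa["hip"], sa["hip"], sa["waist"], sa["chest"],
         0.95 * sa["chest"], 0.78 * sa["chest"]]
    )
    t_torso = _stations_with(y_bot, y_top, stations, [y_hip, y_waist, y_chest])
    a_torso = _profile(ctrl_y, ctrl_a, t_torso)

    def torso_label(y: float) -> int:
        if y < 0.56 * H:
            return PART_IDS["pelvis"]
        if y < 0.605 * H:
            return PART_IDS["abdomen"]
        if y < 0.655 * H:
            return PART_IDS["waist"]
        return PART_IDS["chest"]

    parts.append(
        _tube(np.zeros(3), ey, ex, ez, t_torso, a_torso, rho_t * a_torso,
              zero2(len(t_torso)), angular_resolution, torso_label)
    )

    # --- legs (vertical axes, optional small abduction as lateral shear) ----
    y_calf, y_thigh = st["calf"] * H, st["thigh"] * H
    leg_top = 0.545 * H
    a_ankle = 0.55 * sa["calf"]
    ctrl_y = np.array([0.045 * H, y_calf, 0.285 * H, y_thigh, leg_top])
    ctrl_a = np.array([a_ankle, sa["calf"], 0.82 * sa["thigh"], sa["thigh"],
                       1.02 * sa["thigh"]])
    n_leg = max(20, int(stations * 0.8))
    t_leg = _stations_with(0.045 * H, leg_top, n_leg, [y_calf, y_thigh])
    a_leg = _profile(ctrl_y, ctrl_a, t_leg)
    x_leg = max(1.02 * sa["thigh"], 0.55 * sa["hip"])
    shear = math.tan(math.radians(params.hip_abduction_deg))

    for side, sgn in (("left", +1.0), ("right", -1.0)):
        def leg_label(y: float, side=side) -> int:
            if y < 0.285 * H:
                return PART_IDS[f"lower_{side}_leg"]
            if y < 0.50 * H:
                return PART_IDS[f"upper_{side}_leg"]
            return PART_IDS[f"{side}_hip_junction"]

        centers = np.stack(
            [sgn * shear * (t_leg - t_leg[0]), np.zeros(len(t_leg))], axis=1
        )
        origin = np.array([sgn * x_leg, 0.0, 0.0])
        v, f, lab = _tube(origin, ey, ex, ez, t_leg, a_leg, rho_l * a_leg,
                          centers, angular_resolution, leg_label)
        parts.append((v, f, lab))
        # foot: short elongated stub in front of the ankle
        t_foot = np.array([0.004 * H, 0.045 * H])
        a_foot = np.array([0.80 * a_ankle, 0.85 * a_ankle])
        b_foot = np.array([0.085 * H, 0.055 * H])
        cf = np.array([[0.0, 0.035 * H], [0.0, 0.012 * H]])
        v, f, lab = _tube(origin, ey, ex, ez, t_foot, a_foot, b_foot, cf,
                          angular_resolution, lambda y, s=side: PART_IDS[f"{s}_foot"])
        parts.append((v, f, lab))

    # --- arms (tilted axes, sections perpendicular to the axis) -------------
    alpha = math.radians(params.shoulder_abduction_deg)
    arm_len = 0.34 * H
    a_b = sa["bicep"]
    ctrl_t = np.array([0.0, params.bicep_fraction * arm_len, 0.48 * arm_len,
                       0.75 * arm_len, arm_len])
    ctrl_a = np.array([1.04 * a_b, a_b, 0.82 * a_b, 0.62 * a_b, 0.42 * a_b])
    n_arm = max(16, int(stations * 0.55))
    t_arm = _stations_with(0.0, arm_len, n_arm, [params.bicep_fraction * arm_len])
    a_arm = _profile(ctrl_t, ctrl_a, t_arm)
    y_sh = 0.835 * H
    x_sh = 0.80 * sa["chest"] + 0.85 * a_b

    for side, sgn in (("left", +1.0), ("right", -1.0)):
        d = np.array([sgn * math.sin(alpha), -math.cos(alpha), 0.0])
        u = np.array([sgn * math.cos(alpha), sgn * math.sin(alpha), 0.0])
        origin = np.array([sgn * x_sh, y_sh, 0.0])

        def arm_label(t: float, side=side) -> int:
            if t < 0.10 * arm_len:
                return PART_IDS[f"{side}_shoulder"]
            if t < 0.52 * arm_len:
                return PART_IDS[f"upper_{side}_arm"]
            return PART_IDS[f"lower_{side}_arm"]

        v, f, lab = _tube(origin, d, u, ez, t_arm, a_arm, rho_a * a_arm,
                          zero2(len(t_arm)), angular_resolution, arm_label)
        parts.append((v, f, lab))
        t_hand = np.array([arm_len, 1.17 * arm_len])
        a_hand = np.array([0.45 * a_b, 0.30 * a_b])
        v, f, lab = _tube(origin, d, u, ez, t_hand, a_hand, 0.5 * a_hand,
                          zero2(2), angular_resolution,
                          lambda t, s=side: PART_IDS[f"{s}_hand"])
        parts.append((v, f, lab))

    # arm/torso interference check at mid-torso heights
    for yq in (0.62 * H, 0.72 * H):
        dy = y_sh - yq
        if dy <= 0:
            continue
        arm_x = x_sh + math.tan(alpha) * dy
        arm_halfwidth = float(np.interp(dy / math.cos(alpha), t_arm, a_arm,
                                        right=a_arm[-1])) / math.cos(alpha)
        torso_a = float(_profile(
            np.array([y_bot, y_hip, y_waist, y_chest, 0.80 * H, y_top]),
            np.array([0.97 * sa["hip"], sa["hip"], sa["waist"], sa["chest"],
                      0.95 * sa["chest"], 0.78 * sa["chest"]]),
            np.array([yq]))[0])
        if arm_x - arm_halfwidth < torso_a * 0.98:
            raise ValueError(
                "arm and torso cross-sections intersect at the current pose; "
                "increase shoulder_abduction_deg or reduce girth"
            )

    # --- neck and head ------------------------------------------------------
    a_neck = 0.62 * sa["bicep"] + 0.006 * H
    t_neck = np.linspace(0.845 * H, 0.90 * H, 4)
    v, f, lab = _tube(np.zeros(3), ey, ex, ez, t_neck,
                      np.full(4, a_neck), np.full(4, 0.85 * a_neck),
                      zero2(4), angular_resolution, lambda y: PART_IDS["neck"])
    parts.append((v, f, lab))

    head_lo, head_hi = 0.885 * H, 1.0 * H
    cy, ry = 0.5 * (head_lo + head_hi), 0.5 * (head_hi - head_lo)
    a_head = 0.046 * H
    t_head = cy + ry * np.sin(np.linspace(-0.5 * math.pi * 0.98, 0.5 * math.pi * 0.98, 12))
    shape = np.sqrt(np.clip(1.0 - ((t_head - cy) / ry) ** 2, 1e-4, None))
    v, f, lab = _tube(np.zeros(3), ey, ex, ez, t_head,
                      a_head * shape, 1.2 * a_head * shape,
                      zero2(len(t_head)), angular_resolution,
                      lambda y: PART_IDS["head"])
    parts.append((v, f, lab))

    # --- assemble -----------------------------------------------------------
    verts = []
    faces = []
    labels = []
    off = 0
    for v, f, lab in parts:
        verts.append(v)
        faces.append(f + off)
        labels.append(lab)
        off += len(v)
    vertices = np.vstack(verts)
    vertices[:, 1] = np.maximum(vertices[:, 1], 0.0)
    all_faces = np.vstack(faces)
    all_labels = np.concatenate(labels)

    landmarks = {
        "hip": Landmark(np.array([0.0, y_hip, 0.0]), ey.copy(), "torso"),
        "waist": Landmark(np.array([0.0, y_waist, 0.0]), ey.copy(), "torso"),
        "chest": Landmark(np.array([0.0, y_chest, 0.0]), ey.copy(), "torso"),
        "thigh": Landmark(np.array([x_leg, y_thigh, 0.0]), ey.copy(), "left_leg"),
        "calf": Landmark(np.array([x_leg, y_calf, 0.0]), ey.copy(), "left_leg"),
        "bicep": Landmark(
            np.array([x_sh, y_sh, 0.0])
            + np.array([math.sin(alpha), -math.cos(alpha), 0.0])
            * params.bicep_fraction * arm_len,
            np.array([math.sin(alpha), -math.cos(alpha), 0.0]),
            "left_arm",
        ),
    }
    points = {
        "crown": np.array([0.0, H, 0.0]),
        "left_knee": np.array([x_leg, 0.285 * H, 0.0]),
        "right_knee": np.array([-x_leg, 0.285 * H, 0.0]),
    }
    return BodyMesh(
        vertices=vertices,
        faces=all_faces,
        face_labels=all_labels,
        landmarks=landmarks,
        points=points,
        height=H,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    """One sampled body: measurements requested + shape parameters realized."""

    subject_id: int
    sex: str
    height: float
    requested: dict[str, float]
    params: BodyShapeParams


def sample_cohort(
    target: PopulationSpec,
    n: int,
    seed: int = 0,
    bootstrap_n: int = 3500,
    max_clusters: int = 6,
    source: PopulationSpec | None = None,
) -> list[Subject]:
    """Generate a cohort by the fit -> cluster (BIC) -> importance-sample pipeline.

    A bootstrap measurement table is drawn from ``source`` (a mildly biased
    scan population by default), a sex-specific Gaussian mixture is fitted
    with its component count chosen by BIC, and the mixture is importance
    sampled toward ``target``. Per-subject aspect ratios add depth/width
    variation beyond the measurement vector.
    """
    rng = np.random.default_rng(seed)
    source = source or scan_population(target.sex)
    table = source.sample(bootstrap_n, rng)
    model = fit_population_model(table, max_clusters=max_clusters,
                                 seed=int(rng.integers(2**31)))
    vectors = importance_sample(model, target, n, seed=int(rng.integers(2**31)))
    subjects = []
    for i in range(n):
        vec = vectors[i]
        height = float(np.clip(vec[0], 1.25, 2.15))
        meas = {name: float(vec[2 + j]) for j, name in enumerate(MEASUREMENT_NAMES)}
        for name in MEASUREMENT_NAMES:
            lo, hi = DEFAULT_BOUNDS[name]
            meas[name] = float(np.clip(meas[name], lo * 1.01, hi * 0.99))
        aspects = {
            part: float(np.clip(
                rng.normal(target.aspect_mean, target.aspect_sd), 0.55, 1.0))
            for part in ("torso", "leg", "arm")
        }
        params = shape_from_measurements(meas, target.sex, height, aspects=aspects)
        subjects.append(Subject(i, target.sex, height, meas, params))
    return subjects
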