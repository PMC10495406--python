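"""Agreement and repeatability statistics for anthropometric predictions.

Accuracy against ground truth is summarized by the mean absolute error
MAE = sum |G_i - P_i| / n, the mean absolute percentage error
MAPE = (100/n) * sum |(G_i - P_i) / P_i| (note the prediction in the
denominator), and P90, the 90th percentile of absolute errors.

Repeatability pools, over re-capture sessions of the same subject, the
absolute deviations |pred - session mean| and reports their mean and P90.
Measurement noise is estimated from paired repeat measurements by
symmetrizing the differences (including both d and -d, which removes bias by
construction) and fitting a zero-mean Gaussian to the histogram. Agreement
is summarized Bland-Altman style: bias = mean difference and
95% limits at bias +/- 1.96 sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

PERCENTILE_METHODS = ("linear", "nearest-rank")


def _p90(abs_err: np.ndarray, method: str = "linear") -> float:
    if method == "linear":
        return float(np.percentile(abs_err, 90.0, method="linear"))
    if method == "nearest-rank":
        srt = np.sort(abs_err)
        k = int(np.ceil(0.9 * len(srt))) - 1
        return float(srt[max(k, 0)])
    raise ValueError(f"unknown percentile method {method!r}")


def error_metrics(ground_truth, predictions, percentile_method: str = "linear",
                  mape: bool = True) -> tuple[float, float, float]:
    """(MAE, MAPE %, P90) of predictions against ground truth.

    MAPE uses the prediction as denominator and therefore requires all
    predictions nonzero; pass ``mape=False`` to skip it (returned as nan).
    """
    g = np.asarray(ground_truth, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if g.shape != p.shape or g.ndim != 1 or len(g) < 1:
        raise ValueError("ground truth and predictions must be equal-length 1-D")
    err = np.abs(g - p)
    mae = float(err.mean())
    if mape:
        if np.any(p == 0):
            raise ValueError("MAPE undefined: some predictions are exactly zero")
        mape_val = float(100.0 * np.mean(err / np.abs(p)))
    else:
        mape_val = float("nan")
    return mae, mape_val, _p90(err, percentile_method)


def repeatability(sessions: list[np.ndarray],
                  percentile_method: str = "linear") -> tuple[float, float]:
    """Pooled (mean, P90) of |prediction - session mean| across sessions.

    Each session holds the repeated predictions for one subject under
    re-capture; every session must have at least two entries.
    """
    devs = []
    for i, s in enumerate(sessions):
        s = np.asarray(s, dtype=float)
        if s.ndim != 1 or len(s) < 2:
            raise ValueError(f"session {i} has fewer than 2 renders")
        devs.append(np.abs(s - s.mean()))
    pooled = np.concatenate(devs)
    return float(pooled.mean()), _p90(pooled, percentile_method)


def symmetrize_differences(meas_1, meas_2) -> np.ndarray:
    """Both-direction differences (m1 - m2 and m2 - m1): zero mean exactly."""
    m1 = np.asarray(meas_1, dtype=float)
    m2 = np.asarray(meas_2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("paired measurements must have equal shape")
    d = m1 - m2
    return np.concatenate([d, -d])


def noise_sigma(meas_1, meas_2) -> tuple[float, float]:
    """Noise sd from paired repeats: (gaussian-fit sigma, sample sd).

    Builds the symmetrized difference sample, bins it with Freedman-Diaconis
    widths and least-squares fits a zero-mean Gaussian density; the plain
    sample sd is returned alongside as a cross-check. All-zero differences
    short-circuit to sigma = 0.
    """
    d = symmetrize_differences(meas_1, meas_2)
    if len(d) < 4:
        raise ValueError("need at least 2 measurement pairs")
    sample_sd = float(d.std(ddof=0))
    if np.allclose(d, 0.0):
        return 0.0, 0.0
    counts, edges = np.histogram(d, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, sigma):
        return np.exp(-0.5 * (x / sigma) ** 2) / (np.sqrt(2 * np.pi) * sigma)

    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=[max(sample_sd, 1e-12)],
                            maxfev=10000)
        sigma = float(abs(popt[0]))
    except RuntimeError:
        sigma = sample_sd
    return sigma, sample_sd


def bland_altman(ground_truth, predictions) -> tuple[float, float, float]:
    """(bias, lower limit, upper limit) of the differences P - G.

    Limits of agreement at bias +/- 1.96 sample sd (ddof = 1).
    """
    g = np.asarray(ground_truth, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if g.shape != p.shape or len(g) < 2:
        raise ValueError("Bland-Altman needs >= 2 paired values")
    d = p - g
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


# ---------------------------------------------------------------------------
# Whole-model evaluation
# ---------------------------------------------------------------------------

MEASURE_KEYS = ("hip", "waist", "chest", "thigh", "calf", "bicep", "whr")


@dataclass
class EvalReport:
    """Per-measurement accuracy and repeatability; mm except WHR."""

    accuracy: dict[str, dict[str, float]]         # name -> {mae, mape, p90}
    repeatability: dict[str, dict[str, float]]    # name -> {mean, p90}
    bland_altman_whr: tuple[float, float, float] | None = None
    n_subjects: int = 0
    sessions_per_subject: int = 0
    extras: dict[str, float] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for name in MEASURE_KEYS:
            row = {"measurement": name}
            row |= {f"acc_{k}": v for k, v in self.accuracy.get(name, {}).items()}
            row |= {f"rep_{k}": v
                    for k, v in self.repeatability.get(name, {}).items()}
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "repeatability": self.repeatability,
            "bland_altman_whr": self.bland_altman_whr,
            "n_subjects": self.n_subjects,
            "sessions_per_subject": self.sessions_per_subject,
            "extras": self.extras,
        }


def evaluate_model(predict_fn, cohort, sessions: dict[int, list] | None = None,
                   percentile_method: str = "linear") -> EvalReport:
    """Accuracy (one render per subject) and optional session repeatability.

    ``predict_fn`` maps a MultiViewExample to a MeasurementSet-like object
    (dict access for the named circumferences plus a ``whr`` attribute);
    ``cohort`` is a list of MultiViewExamples with tape-measured ground-truth
    targets; ``sessions`` maps subject id to its list of re-rendered examples.
    """
    gt = {k: [] for k in MEASURE_KEYS}
    pr = {k: [] for k in MEASURE_KEYS}
    for ex in cohort:
        ms = predict_fn(ex)
        for k in MEASURE_KEYS[:-1]:
            gt[k].append(ex.targets.named[k])
            pr[k].append(ms.named[k])
        gt["whr"].append(ex.targets.whr)
        pr["whr"].append(ms.whr)
    accuracy = {}
    for k in MEASURE_KEYS:
        mae, mape, p90 = error_metrics(gt[k], pr[k], percentile_method)
        accuracy[k] = {"mae": mae, "mape": mape, "p90": p90}

    rep = {}
    n_sess = 0
    if sessions:
        per_key: dict[str, list[np.ndarray]] = {k: [] for k in MEASURE_KEYS}
        for sid, renders in sessions.items():
            if len(renders) < 2:
                raise ValueError(f"session for subject {sid} has < 2 renders")
            n_sess = max(n_sess, len(renders))
            preds = [predict_fn(ex) for ex in renders]
            for k in MEASURE_KEYS[:-1]:
                per_key[k].append(np.array([p.named[k] for p in preds]))
            per_key["whr"].append(np.array([p.whr for p in preds]))
        for k in MEASURE_KEYS:
            mean, p90 = repeatability(per_key[k], percentile_method)
            rep[k] = {"mean": mean, "p90": p90}

    ba = bland_altman(gt["whr"], pr["whr"]) if len(cohort) >= 2 else None
    return EvalReport(accuracy=accuracy, repeatability=rep,
                      bland_altman_whr=ba, n_subjects=len(cohort),
                      sessions_per_subject=n_sess)


# ---------------------------------------------------------------------------
# Plots (optional; Agg backend)
# ---------------------------------------------------------------------------

def plot_bland_altman(ground_truth, predictions, path, label: str = "WHR"):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = np.asarray(ground_truth, dtype=float)
    p = np.asarray(predictions, dtype=float)
    bias, lo, hi = bland_altman(g, p)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(0.5 * (g + p), p - g, s=12, alpha=0.6)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel(f"difference ({label})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return bias, lo, hi


def plot_noise_histogram(meas_1, meas_2, path, label: str = "difference (mm)"):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = symmetrize_differences(meas_1, meas_2)
    sigma, sample_sd = noise_sigma(meas_1, meas_2)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(d, bins="fd", density=True, alpha=0.6)
    if sigma > 0:
        x = np.linspace(d.min(), d.max(), 200)
        ax.plot(x, np.exp(-0.5 * (x / sigma) ** 2)
                / (np.sqrt(2 * np.pi) * sigma), "k-")
    ax.set_xlabel(label)
    ax.set_ylabel("density")
    ax.set_title(f"sigma = {sigma:.3g} (sample sd {sample_sd:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return sigma, sample_sd
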