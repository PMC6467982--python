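"""Threshold-crossing detection and the evaluation suite.

A fitted risk model turns each patient's feature rows into a risk trajectory
z(t), updated at every unique timestamp with EHR data (up to shock onset
``t_o`` for shock patients). Detection is the first time z(t) reaches a
fixed threshold (inclusive comparison, pinned so integer-valued toy scores
tie reproducibly); early warning time is EWT = t_o - t_d over true
positives. Patient-level outcomes: a shock patient with any pre-onset
crossing is a true positive, without one a false negative; a non-shock
patient with any crossing is a false positive, otherwise a true negative.

The suite computes the ROC over detection outcomes (threshold grid = every
distinct per-patient trajectory maximum, which makes the curve exact), the
operating point closest to the (FPR 0, TPR 1) corner, sensitivity /
specificity / PPV / median EWT with IQR at a threshold, patient-specific
PPV stratified by deciles of the first supra-threshold risk value z_theta,
patient-resampled bootstrap model comparisons (two-sided Wilcoxon rank-sum),
and EWT as a function of record length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RiskTrajectory:
    """Risk score per unique timestamp for one patient (pre-onset for shock)."""

    patient_id: str
    times: np.ndarray
    z: np.ndarray
    t_o: float | None = None  # shock onset; None for non-shock patients

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.times) != len(self.z):
            raise ValueError("times and z length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if len(self.z) and not np.all(np.isfinite(self.z)):
            raise ValueError("risk values must be finite")

    @property
    def is_shock(self) -> bool:
        return self.t_o is not None

    @property
    def max_z(self) -> float:
        return float(self.z.max()) if len(self.z) else -np.inf

    @property
    def record_length(self) -> float | None:
        """Time from first measurement to shock onset (shock patients only)."""
        if self.t_o is None or len(self.times) == 0:
            return None
        return float(self.t_o - self.times[0])


@dataclass
class DetectionResult:
    patient_id: str
    detected: bool
    t_d: float | None
    z_theta: float | None  # first supra-threshold risk value
    ewt: float | None  # t_o - t_d, shock patients only
    outcome: str  # TP | FP | TN | FN


def detect_crossing(trajectory: RiskTrajectory, theta: float) -> DetectionResult:
    """First threshold crossing: t_d = earliest time with z >= theta."""
    if not np.isfinite(theta):
        if theta == -np.inf:
            pass  # everything crosses immediately; still well-defined
        elif np.isnan(theta):
            raise ValueError("theta must not be NaN")
    if len(trajectory.z) == 0:
        raise ValueError(f"empty trajectory for patient {trajectory.patient_id!r}")
    hits = np.nonzero(trajectory.z >= theta)[0]
    detected = len(hits) > 0
    t_d = float(trajectory.times[hits[0]]) if detected else None
    z_theta = float(trajectory.z[hits[0]]) if detected else None
    if trajectory.is_shock:
        outcome = "TP" if detected else "FN"
        ewt = trajectory.t_o - t_d if detected else None
    else:
        outcome = "FP" if detected else "TN"
        ewt = None
    return DetectionResult(trajectory.patient_id, detected, t_d, z_theta, ewt, outcome)


def _split_classes(trajectories: Sequence[RiskTrajectory]):
    shock = [t for t in trajectories if t.is_shock]
    non = [t for t in trajectories if not t.is_shock]
    return shock, non


def patient_level_roc(
    trajectories: Sequence[RiskTrajectory], thresholds: Sequence[float] | None = None
) -> pd.DataFrame:
    """Patient-level ROC over detection outcomes, plus trapezoidal AUC.

    A patient counts as positive at threshold theta iff their trajectory ever
    reaches theta, so the curve is a function of per-patient maxima; the
    default grid (every distinct maximum plus +inf) therefore yields the
    exact step curve. Returns a DataFrame with columns threshold/fpr/tpr and
    the AUC in ``df.attrs['auc']``.
    """
    shock, non = _split_classes(trajectories)
    if not shock or not non:
        raise ValueError("need at least one shock and one non-shock trajectory")
    max_shock = np.asarray([t.max_z for t in shock])
    max_non = np.asarray([t.max_z for t in non])
    if thresholds is None:
        thresholds = np.unique(np.concatenate([max_shock, max_non, [np.inf]]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    tpr = [(max_shock >= th).mean() for th in thresholds]
    fpr = [(max_non >= th).mean() for th in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    order = np.argsort(roc["fpr"].to_numpy(), kind="stable")
    roc = roc.iloc[order].reset_index(drop=True)
    roc.attrs["auc"] = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    return roc


def optimal_threshold(roc: pd.DataFrame) -> float:
    """Threshold of the ROC point closest to the (FPR 0, TPR 1) corner.

    Ties break toward higher specificity (lower FPR).
    """
    if len(roc) < 2:
        raise ValueError("need at least two ROC points")
    fpr = roc["fpr"].to_numpy()
    tpr = roc["tpr"].to_numpy()
    d2 = fpr**2 + (1.0 - tpr) ** 2
    best = np.nonzero(d2 <= d2.min() + 1e-12)[0]  # tolerance so exact ties tie
    pick = best[np.argmin(fpr[best])]
    return float(roc["threshold"].iloc[pick])


def evaluate_threshold(
    trajectories: Sequence[RiskTrajectory], theta: float
) -> dict:
    """Confusion-matrix metrics and the EWT distribution at a fixed threshold.

    PPV with zero predicted positives is reported as NaN with
    ``ppv_defined=False`` rather than 0.
    """
    results = [detect_crossing(t, theta) for t in trajectories]
    counts = {k: sum(r.outcome == k for r in results) for k in ("TP", "FP", "TN", "FN")}
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    ewts = np.asarray([r.ewt for r in results if r.outcome == "TP"], dtype=float)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv_defined = (tp + fp) > 0
    return {
        "threshold": float(theta),
        "counts": counts,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": tp / (tp + fp) if ppv_defined else np.nan,
        "ppv_defined": ppv_defined,
        "median_ewt": float(np.median(ewts)) if len(ewts) else np.nan,
        "ewt_iqr": (
            (float(np.percentile(ewts, 25)), float(np.percentile(ewts, 75)))
            if len(ewts)
            else (np.nan, np.nan)
        ),
        "ewt_values": ewts,
        "results": results,
    }


def ppv_by_decile(results: Sequence[DetectionResult], n_bins: int = 10) -> pd.DataFrame:
    """Patient-specific PPV stratified by deciles of z_theta.

    Detected patients (TP + FP) are ranked by their first supra-threshold
    risk value and split into ``n_bins`` equal-count bins (sizes differing by
    at most one; ties broken by stable rank); PPV is the TP fraction in each
    bin, reported from lowest to highest decile.
    """
    detected = [r for r in results if r.detected]
    if len(detected) < n_bins:
        raise ValueError(
            f"only {len(detected)} detected patients; use fewer bins than {n_bins}"
        )
    z = np.asarray([r.z_theta for r in detected])
    is_tp = np.asarray([r.outcome == "TP" for r in detected])
    order = np.argsort(z, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(bins, start=1):
        rows.append(
            {
                "decile": i,
                "n": len(idx),
                "z_theta_min": float(z[idx].min()),
                "z_theta_max": float(z[idx].max()),
                "ppv": float(is_tp[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


def _metric_auc(trajectories: Sequence[RiskTrajectory]) -> float:
    return patient_level_roc(trajectories).attrs["auc"]


_METRICS: dict[str, Callable] = {"auc": _metric_auc}


def bootstrap_compare(
    trajectories_a: Sequence[RiskTrajectory],
    trajectories_b: Sequence[RiskTrajectory],
    metric: str | Callable = "auc",
    n_boot: int = 500,
    seed: int = 0,
    max_redraws: int = 1000,
) -> dict:
    """Patient-resampled bootstrap comparison of a metric between two models.

    Both trajectory sets must describe the same patients (paired by index);
    each replicate resamples patients with replacement and evaluates the
    metric under both models on the same resample (common random numbers).
    Replicates where the metric is undefined (a single-class resample) are
    redrawn, with the redraw count reported. The p-value is a two-sided
    Wilcoxon rank-sum test between the two replicate samples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if len(trajectories_a) != len(trajectories_b):
        raise ValueError("trajectory sets must be paired (same patients)")
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    rng = np.random.default_rng(seed)
    n = len(trajectories_a)
    samples_a, samples_b = [], []
    redraws = 0
    while len(samples_a) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            va = fn([trajectories_a[i] for i in idx])
            vb = fn([trajectories_b[i] for i in idx])
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        samples_a.append(va)
        samples_b.append(vb)
    if redraws:
        logger.info("redrew %d degenerate bootstrap replicates", redraws)
    a = np.asarray(samples_a)
    b = np.asarray(samples_b)
    stat, p = stats.ranksums(a, b)
    return {
        "samples_a": a,
        "samples_b": b,
        "statistic": float(stat),
        "p_value": float(p),
        "redraws": redraws,
    }


def ewt_by_record_length(
    results: Sequence[DetectionResult], trajectories: Sequence[RiskTrajectory]
) -> dict:
    """(record length, EWT) pairs over true positives, with Spearman rank correlation.

    Record length is the interval from the first measured data point to shock
    onset. With fewer than three pairs (or constant EWT) the correlation is
    flagged low-confidence and reported as 0 when undefined.
    """
    by_id = {t.patient_id: t for t in trajectories}
    pairs = [
        (by_id[r.patient_id].record_length, r.ewt)
        for r in results
        if r.outcome == "TP" and by_id[r.patient_id].record_length is not None
    ]
    if len(pairs) < 2:
        raise ValueError("need at least two true-positive patients")
    arr = np.asarray(pairs, dtype=float)
    low_n = len(pairs) < 3
    if low_n or np.all(arr[:, 1] == arr[0, 1]) or np.all(arr[:, 0] == arr[0, 0]):
        rho, p = 0.0, np.nan
    else:
        rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
        if np.isnan(rho):
            rho = 0.0
    return {"pairs": arr, "spearman_rho": float(rho), "p_value": p, "low_n": low_n}


@dataclass
class EvaluationReport:
    """Full evaluation output for one model on one cohort."""

    roc: pd.DataFrame
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    median_ewt: float
    ewt_iqr: tuple[float, float]
    ppv_deciles: pd.DataFrame | None
    ewt_vs_length: dict | None
    results: list[DetectionResult] = field(default_factory=list, repr=False)

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "median_ewt": self.median_ewt,
            "ewt_iqr": list(self.ewt_iqr),
            "ppv_decile_trend": (
                float(
                    stats.spearmanr(
                        self.ppv_deciles["decile"], self.ppv_deciles["ppv"]
                    ).statistic
                )
                if self.ppv_deciles is not None and self.ppv_deciles["ppv"].nunique() > 1
                else 0.0
            ),
            "ewt_length_rho": (
                self.ewt_vs_length["spearman_rho"] if self.ewt_vs_length else None
            ),
        }

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.roc.to_csv(out_dir / "roc.csv", index=False)
        pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "detected": r.detected,
                    "t_d": r.t_d,
                    "z_theta": r.z_theta,
                    "ewt": r.ewt,
                    "outcome": r.outcome,
                }
                for r in self.results
            ]
        ).to_csv(out_dir / "detections.csv", index=False)
        if self.ppv_deciles is not None:
            self.ppv_deciles.to_csv(out_dir / "ppv_deciles.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def evaluate_trajectories(
    trajectories: Sequence[RiskTrajectory],
    threshold: float | str = "auto",
    n_deciles: int = 10,
) -> EvaluationReport:
    """ROC, corner-optimal threshold and the full metric suite for one model."""
    roc = patient_level_roc(trajectories)
    theta = optimal_threshold(roc) if threshold == "auto" else float(threshold)
    ev = evaluate_threshold(trajectories, theta)
    results = ev["results"]
    try:
        deciles = ppv_by_decile(results, n_bins=n_deciles)
    except ValueError:
        deciles = None
    try:
        ewt_len = ewt_by_record_length(results, trajectories)
    except ValueError:
        ewt_len = None
    return EvaluationReport(
        roc=roc,
        auc=roc.attrs["auc"],
        threshold=theta,
        sensitivity=ev["sensitivity"],
        specificity=ev["specificity"],
        ppv=ev["ppv"],
        median_ewt=ev["median_ewt"],
        ewt_iqr=ev["ewt_iqr"],
        ppv_deciles=deciles,
        ewt_vs_length=ewt_len,
        results=results,
    )


def risk_trajectories(model, normalizer, matrix) -> list[RiskTrajectory]:
    """Score a feature matrix into one risk trajectory per patient."""
    Z = normalizer.transform(matrix.X)
    z = model.predict_risk(Z)
    out = []
    pids = matrix.patient_ids
    times = matrix.times
    for pid in dict.fromkeys(pids):
        rows = pids == pid
        out.append(
            RiskTrajectory(
                patient_id=pid,
                times=times[rows],
                z=z[rows],
                t_o=matrix.shock_onset.get(pid),
            )
        )
    return out
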