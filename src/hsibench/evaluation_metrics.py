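"""Patient-level sensitivity/specificity curves and the MSS metric.

Performance is aggregated at patient level to preserve clinical validity:
sensitivity and specificity are computed independently for every patient at
each decision threshold t (prediction positive iff score >= t), then averaged
over patients with equal weight regardless of pixel count. Sweeping t over
[0, 1] yields a nonincreasing mean-sensitivity curve and a nondecreasing
mean-specificity curve; their intersection defines the optimal threshold T
and the reported scalar, MSS ("mean over sensitivity and specificity") — the
common curve value at T.

Patients missing a class are dropped from the affected mean with a warning
(their undefined metric is flagged rather than imputed). AUC is the rank
probability that a positive pixel outscores a negative one (ties counted
half) and is patient-averaged for consistency with the curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skmetrics

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class PatientScores:
    """One patient's pixel labels (0/1) and predicted probabilities."""

    patient_id: str
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must have equal length")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class MeanCurves:
    thresholds: np.ndarray
    mean_sensitivity: np.ndarray
    mean_specificity: np.ndarray
    n_patients: int


@dataclass
class MSSResult:
    T: float
    mss: float
    auc_mean: float | None = None
    boundary_flagged: bool = False


def patient_confusion(p: PatientScores, t: float) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) at threshold ``t``; None when undefined."""
    pred = p.scores >= t
    pos = p.labels == 1
    n_pos = int(pos.sum())
    n_neg = int(p.labels.size - n_pos)
    sens = float(np.sum(pred & pos) / n_pos) if n_pos else None
    spec = float(np.sum(~pred & ~pos) / n_neg) if n_neg else None
    return sens, spec


def _patient_curves(p: PatientScores, grid: np.ndarray):
    """Vectorized sensitivity/specificity over all thresholds at once."""
    pos_scores = np.sort(p.scores[p.labels == 1])
    neg_scores = np.sort(p.scores[p.labels == 0])
    sens = spec = None
    if pos_scores.size:
        # predicted positive iff score >= t  ->  count of pos_scores >= t
        sens = 1.0 - np.searchsorted(pos_scores, grid, side="left") / pos_scores.size
    if neg_scores.size:
        spec = np.searchsorted(neg_scores, grid, side="left") / neg_scores.size
    return sens, spec


def mean_curves(patients: list[PatientScores], grid: np.ndarray | None = None) -> MeanCurves:
    """Unweighted patient-mean sensitivity and specificity curves."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sens_list, spec_list = [], []
    for p in patients:
        sens, spec = _patient_curves(p, grid)
        if sens is None or spec is None:
            missing = "positive" if sens is None else "negative"
            logger.warning(
                "patient %s has no %s pixels; dropped from the affected mean",
                p.patient_id, missing,
            )
        if sens is not None:
            sens_list.append(sens)
        if spec is not None:
            spec_list.append(spec)
    if not sens_list or not spec_list:
        raise ValueError("no patient with both classes defined on any curve")
    return MeanCurves(
        thresholds=grid,
        mean_sensitivity=np.mean(sens_list, axis=0),
        mean_specificity=np.mean(spec_list, axis=0),
        n_patients=len(patients),
    )


def find_intersection(curves: MeanCurves) -> MSSResult:
    """Locate T where mean sensitivity and mean specificity cross.

    The crossing is found from the sign change of d(t) = sens(t) - spec(t)
    (nonincreasing) and refined by linear interpolation between the adjacent
    grid points; on an exact-equality plateau T is the plateau midpoint. If d
    never changes sign on [0, 1] the boundary threshold minimizing |d| is
    returned, flagged.
    """
    t = curves.thresholds
    d = curves.mean_sensitivity - curves.mean_specificity
    avg = 0.5 * (curves.mean_sensitivity + curves.mean_specificity)
    zero = d == 0
    if zero.any():
        idx = np.nonzero(zero)[0]
        mid = 0.5 * (t[idx[0]] + t[idx[-1]])
        mss = float(np.interp(mid, t, avg))
        return MSSResult(T=float(mid), mss=mss)
    sign_change = np.nonzero((d[:-1] > 0) & (d[1:] < 0))[0]
    if sign_change.size == 0:
        i = int(np.argmin(np.abs(d)))
        return MSSResult(T=float(t[i]), mss=float(avg[i]), boundary_flagged=True)
    i = int(sign_change[0])
    frac = d[i] / (d[i] - d[i + 1])
    T = float(t[i] + frac * (t[i + 1] - t[i]))
    mss = float(avg[i] + frac * (avg[i + 1] - avg[i]))
    return MSSResult(T=T, mss=mss)


def auc(p: PatientScores) -> float:
    """Rank-based AUC (probability a positive outscores a negative, ties 1/2)."""
    if len(set(p.labels.tolist())) < 2:
        raise ValueError(f"patient {p.patient_id!r} has a single class; AUC undefined")
    return float(_skmetrics.roc_auc_score(p.labels, p.scores))


def f1(labels: np.ndarray, scores: np.ndarray, t: float = 0.5) -> float:
    """F1 at threshold ``t`` with prediction rule score >= t."""
    labels = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) >= t).astype(int)
    return float(_skmetrics.f1_score(labels, pred, zero_division=0))


def evaluate_cohort(
    patients: list[PatientScores], grid: np.ndarray | None = None
) -> MSSResult:
    """Full patient-level evaluation: curves, intersection, mean AUC."""
    curves = mean_curves(patients, grid)
    result = find_intersection(curves)
    aucs = []
    for p in patients:
        try:
            aucs.append(auc(p))
        except ValueError:
            logger.warning("patient %s single-class; dropped from mean AUC", p.patient_id)
    result.auc_mean = float(np.mean(aucs)) if aucs else None
    return result
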