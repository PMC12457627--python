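"""Representative stratified subsampling certified per wavelength by K-S tests.

Evaluating every preprocessing combination on a full cohort is infeasible, so
a small subset is drawn once and reused by *all* combinations (the central
confound control: the model always sees the same pixels in the same order, only
the preprocessing differs). The subset must be distributionally representative,
which is certified per wavelength:

1. randomly draw a fraction (default 1%) of labeled pixels from each patient
   and each class, without replacement (ceil rounding, so tiny classes still
   contribute at least one pixel);
2. for every band, run a two-sample Kolmogorov–Smirnov test of the subset's
   reflectances against the full labeled cohort's (alpha = 0.05);
3. if any band rejects, discard the draw entirely and redraw with a fresh
   stream, until all bands accept (typically fewer than 5 iterations).

The accepted subset is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .hypercube_core import CANCER, NON_MALIGNANT, PatientRecord


class RepresentativenessError(RuntimeError):
    """Raised when no draw passes the per-wavelength K-S certification."""

    def __init__(self, max_iter: int, failing_bands: np.ndarray, min_p: float):
        self.failing_bands = failing_bands
        super().__init__(
            f"no representative subset after {max_iter} draws; "
            f"last draw failed at bands {failing_bands.tolist()} (min p = {min_p:.4g})"
        )


@dataclass
class SubsetIndex:
    """An accepted representative subset.

    ``entries`` is an (n, 3)-shaped list of ``(patient_id, row, col)``;
    ``per_wavelength_p`` holds the K-S p-values of the accepted draw (all
    >= alpha by construction).
    """

    entries: list[tuple[str, int, int]]
    fraction: float
    n_iterations: int
    per_wavelength_p: np.ndarray
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.entries)

    def pixels_for(self, patient_id: str) -> np.ndarray:
        """(k, 2) array of (row, col) for one patient, in subset order."""
        coords = [(r, c) for pid, r, c in self.entries if pid == patient_id]
        return np.array(coords, dtype=int).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["patient_id", "row", "col"])

    def save(self, csv_path: Path, report_path: Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if report_path is not None:
            report = {
                "fraction": self.fraction,
                "alpha": self.alpha,
                "n_iterations": self.n_iterations,
                "n_entries": len(self.entries),
                "per_wavelength_p": [float(p) for p in self.per_wavelength_p],
            }
            Path(report_path).write_text(json.dumps(report, indent=1))


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample K-S test: (D, p).

    D is the maximum absolute difference between the two empirical CDFs; p
    comes from the standard asymptotic two-sample distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires two nonempty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _labeled_values(record: PatientRecord) -> dict[int, np.ndarray]:
    """Per class, the (n_pixels, B) labeled reflectance matrix of one patient."""
    out = {}
    for cls in (NON_MALIGNANT, CANCER):
        rows, cols = np.nonzero(record.mask.labels == cls)
        out[cls] = record.cube.values[rows, cols, :], np.stack([rows, cols], axis=1)
    return out


def sample_representative(
    records: list[PatientRecord],
    fraction: float = 0.01,
    alpha: float = 0.05,
    max_iter: int = 50,
    seed: int = 0,
    per_class: bool = False,
) -> SubsetIndex:
    """Draw a per-patient, per-class stratified subset certified band-by-band.

    By default the K-S comparison population is the full labeled cohort per
    band, pooling both classes; ``per_class=True`` certifies each class's
    subset against that class's cohort distribution instead.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction={fraction} outside (0, 1]")
    per_patient = []  # (pid, cls, values (n,B), coords (n,2))
    for rec in records:
        for cls, (vals, coords) in _labeled_values(rec).items():
            if coords.shape[0] == 0:
                continue
            if coords.shape[0] < 1.0 / fraction:
                raise ValueError(
                    f"patient {rec.patient_id!r} class {cls} has {coords.shape[0]} "
                    f"labeled pixels, fewer than 1/fraction = {1.0 / fraction:.0f}"
                )
            per_patient.append((rec.patient_id, cls, vals, coords))

    full_pooled = np.concatenate([vals for _, _, vals, _ in per_patient], axis=0)
    n_bands = full_pooled.shape[1]
    if per_class:
        full_by_class = {
            cls: np.concatenate(
                [vals for _, c, vals, _ in per_patient if c == cls], axis=0
            )
            for cls in {c for _, c, _, _ in per_patient}
        }

    root = np.random.SeedSequence(seed & 0x7FFFFFFF)
    last_p = None
    for iteration in range(1, max_iter + 1):
        rng = np.random.default_rng(root.spawn(1)[0])
        entries: list[tuple[str, int, int]] = []
        sub_vals = []
        sub_cls = []
        for pid, cls, vals, coords in per_patient:
            n = coords.shape[0]
            take = int(np.ceil(fraction * n))
            idx = rng.choice(n, size=take, replace=False)
            idx.sort()
            entries.extend((pid, int(r), int(c)) for r, c in coords[idx])
            sub_vals.append(vals[idx])
            sub_cls.extend([cls] * take)
        subset = np.concatenate(sub_vals, axis=0)
        sub_cls = np.asarray(sub_cls)

        if per_class:
            p_values = np.empty(n_bands)
            for band in range(n_bands):
                p_band = 1.0
                for cls, full in full_by_class.items():
                    _, p = ks_two_sample(subset[sub_cls == cls, band], full[:, band])
                    p_band = min(p_band, p)
                p_values[band] = p_band
        else:
            p_values = np.array(
                [
                    ks_two_sample(subset[:, band], full_pooled[:, band])[1]
                    for band in range(n_bands)
                ]
            )
        last_p = p_values
        if np.all(p_values >= alpha):
            return SubsetIndex(
                entries=entries,
                fraction=fraction,
                n_iterations=iteration,
                per_wavelength_p=p_values,
                alpha=alpha,
            )
    failing = np.nonzero(last_p < alpha)[0]
    raise RepresentativenessError(max_iter, failing, float(last_p.min()))
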