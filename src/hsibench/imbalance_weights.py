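"""Class- and sample-weight computation for imbalanced pixel cohorts.

With roughly ten non-malignant pixels per cancerous one, an unweighted
binary cross-entropy barely penalizes missed cancer. Two mutually exclusive
loss-weighting schemes are supported:

* **class weights** — ``weight_C = total_pixels / pixels_of_class_C`` (about
  10 for the cancerous class at the study's printed counts), making every
  class contribute equally to the loss;
* **sample weights** — ``weight_{C,P} = total_pixels /
  pixels_of_class_C_of_patient_P``, making every (class, patient) group
  contribute equally, so patients with small annotated lesions are not
  drowned out by patients with large ones.

Sample weights satisfy the equal-attention identity
``weight_{C,P} * count_{C,P} == total`` for every group. When sample weights
are used, class weights are not.

Weights are computed on the training set a fold's model actually sees
(post-filtering, post-subsampling), keeping the loss weighting consistent
with the delivered batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WeightTable:
    """Per-fold weight assignment; exactly one of the two maps is populated."""

    mode: str
    class_weights: dict = field(default_factory=dict)
    sample_weights: dict = field(default_factory=dict)

    def per_sample(self, labels: np.ndarray, patients: list[str]) -> np.ndarray:
        """Expand to one weight per sample."""
        if self.mode == "class":
            return np.array([self.class_weights[int(y)] for y in labels], dtype=float)
        return np.array(
            [self.sample_weights[(int(y), p)] for y, p in zip(labels, patients)],
            dtype=float,
        )

    def as_manifest(self) -> dict:
        return {
            "mode": self.mode,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "sample_weights": {f"{c}|{p}": v for (c, p), v in self.sample_weights.items()},
        }


def class_weights(counts: dict) -> dict:
    """``weight_C = total / count_C`` for every class."""
    if any(n <= 0 for n in counts.values()):
        raise ValueError(f"all class counts must be positive, got {counts}")
    total = sum(counts.values())
    return {cls: total / n for cls, n in counts.items()}


def sample_weights(counts: dict) -> dict:
    """``weight_{C,P} = cohort total / count_{C,P}`` per (class, patient)."""
    if any(n <= 0 for n in counts.values()):
        raise ValueError(f"all (class, patient) counts must be positive, got {counts}")
    total = sum(counts.values())
    return {key: total / n for key, n in counts.items()}


def weight_table(labels: np.ndarray, patients: list[str], mode: str) -> WeightTable:
    """Build a :class:`WeightTable` from a delivered training set."""
    labels = np.asarray(labels).astype(int)
    if mode == "class":
        counts = {int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
        return WeightTable(mode="class", class_weights=class_weights(counts))
    if mode == "sample":
        counts: dict = {}
        for y, p in zip(labels, patients):
            key = (int(y), p)
            counts[key] = counts.get(key, 0) + 1
        return WeightTable(mode="sample", sample_weights=sample_weights(counts))
    raise ValueError(f"unknown weighting mode {mode!r}")
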