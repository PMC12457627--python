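"""Deterministic leave-one-patient-out training around a 3-D CNN classifier.

This module owns the three confound controls that make preprocessing
combinations comparable:

1. **A fixed cross-validation plan.** Leave-one-patient-out: each patient is
   the test set exactly once; three validation patients are drawn
   deterministically from ``(mapping_seed, test id)`` and the *same* test ->
   validation mapping is reused by every combination.
2. **Fixed model state.** The classifier is rebuilt from the same
   ``init_seed`` for every fold and combination, dropout uses its own seeded
   stream, and training is pure numpy, so two runs with identical inputs are
   bit-identical on one platform (cross-platform bit-identity is not promised).
3. **Same data in the same order.** The representative subset is permuted once
   with ``shuffle_seed``; artifact filtering may remove entries but never
   reorders survivors, so the delivered sample order (by pixel identity) is
   identical across combinations.

The classifier is a single Inception-style block of parallel 3-D convolutions
('same'-padded throughout, so branch outputs concatenate cleanly): a 1x1x1
branch, a 1x1x1 -> 3x3x3 branch, and a 3x3x3 max-pool -> 1x1x1 branch, all
ReLU, followed by flatten -> dense -> dropout -> a single sigmoid unit.
Training minimizes weighted binary cross-entropy with Adam and stops early
when the pooled-validation F1 (probability threshold 0.5) fails to improve
for more than ``patience`` epochs; the best-validation weights are restored.

Forward/backward passes and Adam are implemented directly in numpy (no deep
learning backend), which keeps the determinism contract exact.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .hypercube_core import PatientRecord
from .imbalance_weights import WeightTable, weight_table
from .preprocessing_ops import PreprocessingCombination, apply_combination
from .representative_sampling import SubsetIndex


# ---------------------------------------------------------------------------
# Cross-validation planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    test_patient: str
    validation_patients: tuple
    train_patients: tuple

    def __post_init__(self):
        sets = [{self.test_patient}, set(self.validation_patients), set(self.train_patients)]
        for a, b in itertools.combinations(sets, 2):
            if a & b:
                raise ValueError("fold sets must be disjoint")


@dataclass(frozen=True)
class CVPlan:
    folds: tuple
    mapping_seed: int

    def patient_ids(self) -> list[str]:
        return [f.test_patient for f in self.folds]

    def to_json(self) -> str:
        payload = {
            "mapping_seed": self.mapping_seed,
            "folds": [
                {
                    "test": f.test_patient,
                    "validation": list(f.validation_patients),
                    "train": list(f.train_patients),
                }
                for f in self.folds
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Path) -> "CVPlan":
        payload = json.loads(Path(path).read_text())
        folds = tuple(
            FoldPlan(f["test"], tuple(f["validation"]), tuple(f["train"]))
            for f in payload["folds"]
        )
        return cls(folds=folds, mapping_seed=payload["mapping_seed"])


def _stable_id_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def make_cv_plan(patient_ids: list[str], n_val: int = 3, mapping_seed: int = 0) -> CVPlan:
    """One leave-one-patient-out fold per patient with a fixed validation map.

    Validation patients for test patient X are a seeded draw without
    replacement from the non-test patients, a pure function of
    ``(mapping_seed, X)`` — the identical plan is consumed by every
    combination and rerun.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < n_val + 2:
        raise ValueError(
            f"need at least {n_val + 2} patients for {n_val} validation + "
            f"nonempty train, got {len(ids)}"
        )
    folds = []
    for test in ids:
        others = sorted(p for p in ids if p != test)
        rng = np.random.default_rng(
            np.random.SeedSequence([mapping_seed & 0x7FFFFFFF, _stable_id_hash(test)])
        )
        val = tuple(sorted(rng.choice(len(others), size=n_val, replace=False).tolist()))
        validation = tuple(others[i] for i in val)
        train = tuple(p for p in others if p not in validation)
        folds.append(FoldPlan(test, validation, train))
    return CVPlan(folds=tuple(folds), mapping_seed=mapping_seed)


# ---------------------------------------------------------------------------
# Model specification and training configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the Inception-style 3-D CNN.

    Branch filter widths are deliberately small; they are configurable since
    only the block structure, not exact filter counts, is fixed by design.
    """

    patch_size: int = 3
    n_bands: int = 92
    b1_filters: int = 6
    b2_reduce: int = 4
    b2_filters: int = 6
    b3_filters: int = 4
    dense_units: int = 32
    dropout_rate: float = 0.2

    @property
    def concat_channels(self) -> int:
        return self.b1_filters + self.b2_filters + self.b3_filters


@dataclass(frozen=True)
class TrainConfig:
    """Training loop parameters; defaults are the study's values."""

    max_epochs: int = 50
    batch_size: int = 500
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    patience: int = 5
    #: global-norm gradient clip; sample weights of ~10-60x make early
    #: batches spiky enough to kill every ReLU without it (None disables)
    clipnorm: float | None = 1.0
    init_seed: int = 1
    shuffle_seed: int = 2
    dropout_seed: int = 3
    #: cap on evaluated test-patient pixels (None = all); seeded subsample.
    eval_max_pixels: int | None = None

    def __post_init__(self):
        for name in ("max_epochs", "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def desk_scale_config(**overrides) -> TrainConfig:
    """Desk-scale training configuration for small synthetic cohorts.

    At a few hundred training samples per fold the study-scale settings
    (batch 500, lr 1e-4) yield too few, too small optimizer steps for any
    learning to be observable, so desk runs use batch 16 / lr 3e-4 / at most
    10 epochs by default. Everything remains overridable.
    """
    params = dict(max_epochs=10, batch_size=16, learning_rate=3e-4)
    params.update(overrides)
    return TrainConfig(**params)


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------

def _conv3d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """'same'-padded 3-D convolution; returns (out, padded input for backward)."""
    kh, kw, kd, _, cout = W.shape
    ph, pw, pd = kh // 2, kw // 2, kd // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (pd, pd), (0, 0)))
    n, h, w, d = x.shape[:4]
    out = np.broadcast_to(b, (n, h, w, d, cout)).copy()
    for i in range(kh):
        for j in range(kw):
            for k in range(kd):
                out += np.tensordot(
                    xp[:, i : i + h, j : j + w, k : k + d, :], W[i, j, k], axes=([4], [0])
                )
    return out, xp


def _conv3d_backward(g: np.ndarray, xp: np.ndarray, W: np.ndarray, need_dx: bool):
    kh, kw, kd, cin, cout = W.shape
    n, h, w, d = g.shape[:4]
    dW = np.empty_like(W)
    db = g.sum(axis=(0, 1, 2, 3))
    for i in range(kh):
        for j in range(kw):
            for k in range(kd):
                dW[i, j, k] = np.tensordot(
                    xp[:, i : i + h, j : j + w, k : k + d, :], g,
                    axes=([0, 1, 2, 3], [0, 1, 2, 3]),
                )
    dx = None
    if need_dx:
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                for k in range(kd):
                    dxp[:, i : i + h, j : j + w, k : k + d, :] += np.tensordot(
                        g, W[i, j, k], axes=([4], [1])
                    )
        ph, pw, pd = kh // 2, kw // 2, kd // 2
        dx = dxp[:, ph : ph + h, pw : pw + w, pd : pd + d, :]
    return dW, db, dx


def _maxpool3_same(x: np.ndarray) -> np.ndarray:
    """3x3x3 stride-1 'same' max pool (gradient never needed: pool feeds
    directly off the input layer)."""
    n, h, w, d, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
    out = np.full(x.shape, -np.inf, dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                np.maximum(out, xp[:, i : i + h, j : j + w, k : k + d, :], out=out)
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Inception3D:
    """Single-block Inception-style 3-D CNN for binary patch classification.

    Pure-numpy forward/backward with Adam; identical ``(spec, init_seed)``
    always yields identical initial parameters, and the dropout stream is
    fixed by ``dropout_seed``.
    """

    def __init__(self, spec: ModelSpec, init_seed: int = 1, dropout_seed: int = 3):
        self.spec = spec
        self.init_seed = init_seed
        self._dropout_rng = np.random.default_rng(dropout_seed & 0x7FFFFFFF)
        rng = np.random.default_rng(init_seed & 0x7FFFFFFF)
        p, bnd = spec.patch_size, spec.n_bands

        # Glorot-normal: keeps early activations tame enough that aggressive
        # loss weights cannot kill every ReLU in the first epochs (He-scaled
        # 1x1x1 convs with fan-in 1 proved collapse-prone here)
        def glorot(shape, fan_in, fan_out):
            std = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, std, size=shape).astype(np.float32)

        flat = p * p * bnd * spec.concat_channels
        self.params = {
            "c1_W": glorot((1, 1, 1, 1, spec.b1_filters), 1, spec.b1_filters),
            "c1_b": np.zeros(spec.b1_filters, dtype=np.float32),
            "c2r_W": glorot((1, 1, 1, 1, spec.b2_reduce), 1, spec.b2_reduce),
            "c2r_b": np.zeros(spec.b2_reduce, dtype=np.float32),
            "c2_W": glorot(
                (3, 3, 3, spec.b2_reduce, spec.b2_filters),
                27 * spec.b2_reduce, 27 * spec.b2_filters,
            ),
            "c2_b": np.zeros(spec.b2_filters, dtype=np.float32),
            "c3_W": glorot((1, 1, 1, 1, spec.b3_filters), 1, spec.b3_filters),
            "c3_b": np.zeros(spec.b3_filters, dtype=np.float32),
            "d1_W": glorot((flat, spec.dense_units), flat, spec.dense_units),
            "d1_b": np.zeros(spec.dense_units, dtype=np.float32),
            "out_W": glorot((spec.dense_units, 1), spec.dense_units, 1),
            "out_b": np.zeros(1, dtype=np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False):
        """X: (n, P, P, B). Returns probabilities (n,) and a cache for backward."""
        P = self.params
        x = X[..., None].astype(np.float32, copy=False)
        a1, xp1 = _conv3d_same(x, P["c1_W"], P["c1_b"])
        b1 = np.maximum(a1, 0)
        a2r, xp2r = _conv3d_same(x, P["c2r_W"], P["c2r_b"])
        h2 = np.maximum(a2r, 0)
        a2, xp2 = _conv3d_same(h2, P["c2_W"], P["c2_b"])
        b2 = np.maximum(a2, 0)
        pooled = _maxpool3_same(x)
        a3, xp3 = _conv3d_same(pooled, P["c3_W"], P["c3_b"])
        b3 = np.maximum(a3, 0)
        cat = np.concatenate([b1, b2, b3], axis=-1)
        flat = cat.reshape(cat.shape[0], -1)
        ad = flat @ P["d1_W"] + P["d1_b"]
        h = np.maximum(ad, 0)
        if training and self.spec.dropout_rate > 0:
            keep = (
                self._dropout_rng.random(h.shape, dtype=np.float32)
                >= self.spec.dropout_rate
            ).astype(np.float32) / np.float32(1.0 - self.spec.dropout_rate)
        else:
            keep = None
        hd = h * keep if keep is not None else h
        z = hd @ P["out_W"] + P["out_b"]
        prob = _sigmoid(z)[:, 0]
        cache = dict(
            xp1=xp1, a1=a1, xp2r=xp2r, a2r=a2r, h2=h2, xp2=xp2, a2=a2,
            xp3=xp3, a3=a3, cat_shape=cat.shape, flat=flat, ad=ad, h=h,
            keep=keep, hd=hd,
        )
        return prob, cache

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic inference (dropout off), batched."""
        out = np.empty(X.shape[0], dtype=np.float64)
        for start in range(0, X.shape[0], batch_size):
            prob, _ = self.forward(X[start : start + batch_size], training=False)
            out[start : start + prob.size] = prob
        return out

    # -- backward + Adam ---------------------------------------------------

    def _backward(self, prob, y, w, cache):
        """Weighted BCE gradient; returns grads dict. Loss uses weights
        normalized by their sum, so dL/dz = w (p - y) / sum(w)."""
        P, s = self.params, self.spec
        n = prob.size
        wsum = np.float32(w.sum())
        dz = ((w * (prob - y)) / wsum).astype(np.float32)[:, None]
        g = {}
        g["out_W"] = cache["hd"].T @ dz
        g["out_b"] = dz.sum(axis=0)
        dhd = dz @ P["out_W"].T
        if cache["keep"] is not None:
            dhd = dhd * cache["keep"]
        dh = dhd * (cache["ad"] > 0)
        g["d1_W"] = cache["flat"].T @ dh
        g["d1_b"] = dh.sum(axis=0)
        dflat = dh @ P["d1_W"].T
        dcat = dflat.reshape(cache["cat_shape"])
        f1, f2 = s.b1_filters, s.b2_filters
        db1 = dcat[..., :f1] * (cache["a1"] > 0)
        db2 = dcat[..., f1 : f1 + f2] * (cache["a2"] > 0)
        db3 = dcat[..., f1 + f2 :] * (cache["a3"] > 0)
        g["c1_W"], g["c1_b"], _ = _conv3d_backward(db1, cache["xp1"], P["c1_W"], False)
        g["c2_W"], g["c2_b"], dh2 = _conv3d_backward(db2, cache["xp2"], P["c2_W"], True)
        da2r = dh2 * (cache["a2r"] > 0)
        g["c2r_W"], g["c2r_b"], _ = _conv3d_backward(da2r, cache["xp2r"], P["c2r_W"], False)
        g["c3_W"], g["c3_b"], _ = _conv3d_backward(db3, cache["xp3"], P["c3_W"], False)
        return g

    def train_step(self, X, y, w, cfg: TrainConfig) -> float:
        prob, cache = self.forward(X, training=True)
        grads = self._backward(prob, y.astype(np.float32), w.astype(np.float32), cache)
        if cfg.clipnorm is not None:
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > cfg.clipnorm:
                scale = np.float32(cfg.clipnorm / gnorm)
                grads = {k: g * scale for k, g in grads.items()}
        self._adam_t += 1
        t, eps = self._adam_t, 1e-7
        lr = cfg.learning_rate
        for key, gval in grads.items():
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= cfg.beta1
            m += (1 - cfg.beta1) * gval
            v *= cfg.beta2
            v += (1 - cfg.beta2) * gval**2
            mhat = m / (1 - cfg.beta1**t)
            vhat = v / (1 - cfg.beta2**t)
            self.params[key] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)
        p = np.clip(prob.astype(np.float64), 1e-7, 1 - 1e-7)
        return float(-(w * (y * np.log(p) + (1 - y) * np.log1p(-p))).sum() / w.sum())

    def snapshot(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: dict) -> None:
        self.params = {k: v.copy() for k, v in snap.items()}

    def param_checksum(self) -> str:
        digest = hashlib.sha256()
        for key in sorted(self.params):
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(self.params[key]).tobytes())
        return digest.hexdigest()


def build_model(spec: ModelSpec, init_seed: int = 1, dropout_seed: int = 3) -> Inception3D:
    """Construct the classifier with reproducible initial state."""
    if spec.patch_size % 2 != 1:
        raise ValueError("patch_size must be odd")
    return Inception3D(spec, init_seed=init_seed, dropout_seed=dropout_seed)


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop when the monitored score has not strictly improved for more than
    ``patience`` epochs; remembers which epoch was best."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self._since = 0
        self.epoch = 0

    def update(self, score: float) -> bool:
        """Record one epoch's score; returns True if training should stop."""
        self.epoch += 1
        if score > self.best:
            self.best = score
            self.best_epoch = self.epoch
            self._since = 0
        else:
            self._since += 1
        return self._since > self.patience


def f1_at_threshold(labels: np.ndarray, scores: np.ndarray, t: float = 0.5) -> float:
    """F1 with prediction rule score >= t; 0 when precision+recall is 0."""
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Fold training
# ---------------------------------------------------------------------------

def train_model(
    Xtr, ytr, wtr, Xval, yval, cfg: TrainConfig, spec: ModelSpec
) -> tuple[Inception3D, dict]:
    """Train one fold's model with early stopping on pooled-validation F1.

    Batches are sequential slices of the delivered order (no reshuffling, so
    the order contract holds exactly). Returns the model (best-validation
    weights restored) and a history dict.
    """
    model = build_model(spec, init_seed=cfg.init_seed, dropout_seed=cfg.dropout_seed)
    stopper = EarlyStopper(patience=cfg.patience)
    best_snap = model.snapshot()
    val_flagged = bool(yval.sum() == 0)
    history = {"train_loss": [], "val_f1": []}
    for _epoch in range(cfg.max_epochs):
        losses = []
        for start in range(0, Xtr.shape[0], cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            losses.append(model.train_step(Xtr[sl], ytr[sl], wtr[sl], cfg))
        val_f1 = 0.0 if val_flagged else f1_at_threshold(yval, model.predict(Xval))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_f1"].append(val_f1)
        # snapshot on ties too (later epoch wins), so a flat-F1 run keeps its
        # most-trained weights; the patience counter still requires strict
        # improvement, matching the "did not improve" stopping rule
        snapshot_now = val_f1 >= stopper.best
        stop = stopper.update(val_f1)
        if snapshot_now:
            best_snap = model.snapshot()
        if stop:
            break
    model.restore(best_snap)
    history["epochs_run"] = stopper.epoch
    history["best_epoch"] = stopper.best_epoch
    history["validation_flagged"] = val_flagged
    return model, history


# ---------------------------------------------------------------------------
# Combination run
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    """Per-fold test-patient scores plus the reproducibility manifest."""

    #: test patient id -> dict(labels, scores, coords)
    patient_scores: dict
    manifest: dict
    #: test patient id -> delivered training order [(pid, row, col), ...]
    fold_train_order: dict


def score_checksum(labels: np.ndarray, scores: np.ndarray) -> str:
    digest = hashlib.sha256()
    digest.update(np.asarray(labels, dtype=np.int8).tobytes())
    digest.update(np.asarray(scores, dtype="<f8").tobytes())
    return digest.hexdigest()


def _permuted_entries(subset: SubsetIndex, shuffle_seed: int) -> list[tuple[str, int, int]]:
    """One deterministic permutation of the subset — shared by all combos."""
    rng = np.random.default_rng(shuffle_seed & 0x7FFFFFFF)
    order = rng.permutation(len(subset.entries))
    return [subset.entries[i] for i in order]


def train_combination(
    records: list[PatientRecord],
    subset: SubsetIndex,
    combo: PreprocessingCombination,
    plan: CVPlan,
    cfg: TrainConfig,
    model_spec: ModelSpec | None = None,
) -> TrainResult:
    """Run every LOOCV fold of ``plan`` for one preprocessing combination.

    Per patient, preprocessing runs once (it is fold-independent); each fold
    then trains a freshly initialized model on the permuted subset entries of
    its train patients, early-stops on its validation patients' subset pixels,
    and scores the test patient's full labeled (non-excluded) pixel set —
    optionally capped by ``cfg.eval_max_pixels`` via a seeded subsample.
    """
    by_id = {rec.patient_id: rec for rec in records}
    entries = _permuted_entries(subset, cfg.shuffle_seed)
    pixels_by_patient: dict[str, list] = {}
    for pid, r, c in entries:
        pixels_by_patient.setdefault(pid, []).append((r, c))

    trace: list[str] = []
    subset_patches = {}  # pid -> (lookup, PatchSet)
    eval_sets = {}  # pid -> PatchSet over all labeled non-excluded pixels
    for pid, pix in pixels_by_patient.items():
        ps = apply_combination(
            by_id[pid], combo, pixels=np.array(pix),
            trace=trace if not trace else None,
        )
        lookup = {(int(r), int(c)): i for i, (r, c) in enumerate(ps.pixel_coords)}
        subset_patches[pid] = (lookup, ps)
    for pid in plan.patient_ids():
        full = apply_combination(by_id[pid], combo)
        if cfg.eval_max_pixels is not None and len(full) > cfg.eval_max_pixels:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [cfg.shuffle_seed & 0x7FFFFFFF, _stable_id_hash(pid + "/eval")]
                )
            )
            keep = np.sort(rng.choice(len(full), size=cfg.eval_max_pixels, replace=False))
            full = type(full)(
                full.patches[keep], full.labels[keep], full.pixel_coords[keep], pid
            )
        eval_sets[pid] = full

    if model_spec is None:
        any_ps = next(iter(subset_patches.values()))[1]
        model_spec = ModelSpec(
            patch_size=combo.patch_size, n_bands=any_ps.patches.shape[3]
        )

    def gather(patient_set):
        """Delivered-order samples for a set of patients (filter-stable)."""
        X, y, pids, coords = [], [], [], []
        for pid, r, c in entries:
            if pid not in patient_set:
                continue
            lookup, ps = subset_patches[pid]
            idx = lookup.get((r, c))
            if idx is None:  # removed by the exclusion mask
                continue
            X.append(ps.patches[idx])
            y.append(ps.labels[idx])
            pids.append(pid)
            coords.append((pid, r, c))
        X = np.stack(X).astype(np.float32) if X else np.empty((0, 1, 1, 1), np.float32)
        return X, np.asarray(y, dtype=np.int8), pids, coords

    patient_scores = {}
    fold_train_order = {}
    fold_manifests = []
    for fold in plan.folds:
        Xtr, ytr, tr_pids, tr_coords = gather(set(fold.train_patients))
        Xval, yval, _, _ = gather(set(fold.validation_patients))
        wt: WeightTable = weight_table(ytr, tr_pids, combo.weighting)
        wtr = wt.per_sample(ytr, tr_pids)
        model, history = train_model(Xtr, ytr, wtr, Xval, yval, cfg, model_spec)
        ev = eval_sets[fold.test_patient]
        scores = model.predict(ev.patches.astype(np.float32))
        patient_scores[fold.test_patient] = {
            "labels": ev.labels.astype(np.int8),
            "scores": scores,
            "coords": ev.pixel_coords,
        }
        fold_train_order[fold.test_patient] = tr_coords
        fold_manifests.append(
            {
                "test_patient": fold.test_patient,
                "validation_patients": list(fold.validation_patients),
                "n_train": int(ytr.size),
                "n_validation": int(yval.size),
                "n_eval": int(ev.labels.size),
                "epochs_run": history["epochs_run"],
                "best_epoch": history["best_epoch"],
                "validation_flagged": history["validation_flagged"],
                "weighting": wt.as_manifest()["mode"],
                "score_checksum": score_checksum(ev.labels, scores),
            }
        )

    manifest = {
        "combo": combo.as_record(),
        "pipeline_stages": trace,
        "seeds": {
            "init_seed": cfg.init_seed,
            "shuffle_seed": cfg.shuffle_seed,
            "dropout_seed": cfg.dropout_seed,
            "mapping_seed": plan.mapping_seed,
        },
        "train_config": {
            "max_epochs": cfg.max_epochs,
            "batch_size": cfg.batch_size,
            "learning_rate": cfg.learning_rate,
            "beta1": cfg.beta1,
            "beta2": cfg.beta2,
            "patience": cfg.patience,
            "eval_max_pixels": cfg.eval_max_pixels,
        },
        "model_spec": asdict(model_spec),
        "subset": {"fraction": subset.fraction, "n_entries": len(subset)},
        "folds": fold_manifests,
    }
    return TrainResult(
        patient_scores=patient_scores,
        manifest=manifest,
        fold_train_order=fold_train_order,
    )
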