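"""Synthetic cohorts of labeled hyperspectral cubes.

The study's clinical cubes (resected colorectal specimens imaged at 500-1000 nm)
are available only on request, so this module generates cohorts with the same
statistical structure: per-pixel reflectance spectra drawn from smooth class
signatures (sums of Gaussian bumps over wavelength), an ~10:1
non-malignant:cancer pixel imbalance realised as one blob-shaped lesion per
patient whose area varies across patients, per-patient multiplicative/additive
signature perturbation (inter-patient spectral variation), per-voxel additive
noise, and the two optical artifacts that motivate the filtering stage:

* **blood** — contiguous streaks whose spectra equal the cancer signature plus
  a Gaussian bump centred at 515 nm. In the retained bands (>= 540 nm) blood is
  therefore nearly indistinguishable from cancer — the false-positive mechanism
  the filtering stage exists to fix — while its mean reflectance over the
  510-570 nm window (metric B, computed on the full-band cube before band
  exclusion) is clearly elevated above both tissue classes, so a blood filter
  with threshold between the tissue and blood B-levels isolates it.
* **glare** — small disks of near-zero flat reflectance, emulating specular
  pixels whose calibrated reflectance clips to an unreliable dark plateau;
  these are caught by the light filter's low-broadband-mean predicate.

Cohort generation labels its own artifact pixels ``MARGIN`` so they never enter
the labeled sample set. :func:`inject_artifacts` instead overlays artifact
spectra while *keeping* the underlying tissue labels — emulating unannotated
blood lying on top of annotated tissue, the failure mode in which blood pixels
are evaluated as negatives and misclassified as cancer.

Determinism: every patient has its own pseudo-random stream derived from
``(seed, patient_id)``, so cohorts are bit-identical across runs and stable
under patient reordering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hypercube_core import (
    CANCER,
    MARGIN,
    NON_MALIGNANT,
    AnnotationMask,
    Hypercube,
    PatientRecord,
    WavelengthGrid,
)


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


@dataclass(frozen=True)
class SpectralModel:
    """Class signatures and nuisance parameters of the synthetic spectra.

    Signatures are parametrized as ``base + sum(amp * exp(-(λ-center)²/2w²))``
    and evaluated on a wavelength grid via :meth:`signature`. All expected
    reflectances lie in [0, 1] before noise.
    """

    #: class name -> (base, [(amplitude, center_nm, width_nm), ...])
    class_bumps: dict = field(
        default_factory=lambda: {
            "non_malignant": (0.08, [(0.05, 545.0, 25.0), (0.50, 800.0, 120.0)]),
            "cancer": (0.10, [(0.06, 545.0, 25.0), (0.36, 810.0, 130.0)]),
        }
    )
    #: blood = cancer signature + this bump (elevated 510-570 nm mean).
    blood_bump: tuple = (0.35, 515.0, 11.0)
    #: flat reflectance plateau of glare pixels.
    glare_level: float = 0.05
    #: sd of the per-patient multiplicative gain (mean 1).
    patient_offset_sd: float = 0.05
    #: sd of the per-patient additive offset (mean 0).
    patient_shift_sd: float = 0.01
    #: per-voxel additive Gaussian noise sd.
    noise_sd: float = 0.02

    def signature(self, name: str, grid: WavelengthGrid) -> np.ndarray:
        """Expected reflectance curve of ``name`` on ``grid`` (clipped to [0,1])."""
        lam = grid.centers_nm
        if name == "blood":
            amp, center, width = self.blood_bump
            curve = self.signature("cancer", grid) + amp * _gauss(lam, center, width)
        elif name == "glare":
            curve = np.full(lam.shape, self.glare_level)
        else:
            base, bumps = self.class_bumps[name]
            curve = base + sum(a * _gauss(lam, c, w) for a, c, w in bumps)
        return np.clip(curve, 0.0, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Geometry and composition of a synthetic cohort.

    Defaults are desk-scale: 10 patients of 64x64 pixels on the full
    100-band 500-995 nm grid, targeting the study's ~10:1 class imbalance
    (``cancer_fraction`` 0.09 of labeled pixels). Full-size 480x640 cohorts
    are supported but not default.
    """

    n_patients: int = 10
    height: int = 64
    width: int = 64
    grid: WavelengthGrid = field(
        default_factory=lambda: WavelengthGrid.from_range(500.0, 995.0, 5.0)
    )
    cancer_fraction: float = 0.09
    #: sd of the log lesion-area multiplier across patients.
    cancer_area_spread: float = 0.35
    blood_fraction: float = 0.0
    glare_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("cancer_fraction", "blood_fraction", "glare_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.blood_fraction + self.glare_fraction >= 1.0:
            raise ValueError("artifact fractions must sum to < 1")


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Independent stream per (seed, patient_id), stable across runs."""
    digest = hashlib.sha256(patient_id.encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, int.from_bytes(digest[:4], "big")])
    )


def _lesion_mask(rng: np.random.Generator, h: int, w: int, area: float) -> np.ndarray:
    """Elliptical blob of approximately ``area`` pixels, away from borders."""
    aspect = rng.uniform(0.6, 1.6)
    ry = max(2.0, np.sqrt(area / np.pi * aspect))
    rx = max(2.0, area / np.pi / ry)
    cy = rng.uniform(ry + 2, h - ry - 2) if h > 2 * ry + 4 else h / 2
    cx = rng.uniform(rx + 2, w - rx - 2) if w > 2 * rx + 4 else w / 2
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _blood_streaks(rng: np.random.Generator, h: int, w: int, n_pixels: int) -> np.ndarray:
    """Contiguous random-walk streaks, dilated to width ~2, totalling ~n_pixels."""
    mask = np.zeros((h, w), dtype=bool)
    while mask.sum() < n_pixels:
        r, c = rng.integers(0, h), rng.integers(0, w)
        length = int(rng.integers(max(4, h // 4), max(8, h)))
        for _ in range(length):
            mask[r, c] = True
            dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
            r = int(np.clip(r + dr, 0, h - 1))
            c = int(np.clip(c + dc, 0, w - 1))
        mask = ndimage.binary_dilation(mask, iterations=1)
        if mask.sum() >= n_pixels:
            break
    # trim overshoot deterministically (row-major order)
    extra = mask.sum() - n_pixels
    if extra > 0:
        rs, cs = np.nonzero(mask)
        mask[rs[-extra:], cs[-extra:]] = False
    return mask


def _glare_disks(rng: np.random.Generator, h: int, w: int, n_pixels: int) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    while mask.sum() < n_pixels:
        r = rng.uniform(1.5, max(2.5, min(h, w) / 12))
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    extra = mask.sum() - n_pixels
    if extra > 0:
        rs, cs = np.nonzero(mask)
        mask[rs[-extra:], cs[-extra:]] = False
    return mask


def _synthesize_patient(
    pid: str, spec: CohortSpec, model: SpectralModel
) -> PatientRecord:
    rng = _patient_rng(spec.seed, pid)
    h, w = spec.height, spec.width
    grid = spec.grid

    area = spec.cancer_fraction * h * w * float(
        np.exp(rng.normal(0.0, spec.cancer_area_spread))
    )
    lesion = _lesion_mask(rng, h, w, area)
    labels = np.full((h, w), NON_MALIGNANT, dtype=np.uint8)
    labels[lesion] = CANCER
    ring = ndimage.binary_dilation(lesion, iterations=1) & ~lesion
    labels[ring] = MARGIN

    gain = 1.0 + rng.normal(0.0, model.patient_offset_sd)
    shift = rng.normal(0.0, model.patient_shift_sd)
    sig_nm = np.clip(model.signature("non_malignant", grid) * gain + shift, 0.0, 1.0)
    sig_ca = np.clip(model.signature("cancer", grid) * gain + shift, 0.0, 1.0)

    values = np.empty((h, w, len(grid)))
    values[~lesion] = sig_nm
    values[lesion] = sig_ca

    # cohort-spec artifacts: spectra replaced AND pixels pulled out of the
    # labeled classes (MARGIN), so they enter filtering but never the samples
    n_px = h * w
    if spec.blood_fraction > 0:
        streaks = _blood_streaks(rng, h, w, int(round(spec.blood_fraction * n_px)))
        values[streaks] = np.clip(model.signature("blood", grid) * gain + shift, 0.0, 1.0)
        labels[streaks] = MARGIN
    if spec.glare_fraction > 0:
        disks = _glare_disks(rng, h, w, int(round(spec.glare_fraction * n_px)))
        values[disks] = model.signature("glare", grid)
        labels[disks] = MARGIN

    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    return PatientRecord(pid, Hypercube(values, grid), AnnotationMask(labels))


def generate_cohort(spec: CohortSpec, model: SpectralModel | None = None) -> list[PatientRecord]:
    """Generate a deterministic cohort of labeled synthetic patients."""
    model = model if model is not None else SpectralModel()
    return [
        _synthesize_patient(f"p{i:03d}", spec, model) for i in range(spec.n_patients)
    ]


def inject_artifacts(
    record: PatientRecord,
    model: SpectralModel,
    blood_fraction: float = 0.0,
    glare_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[PatientRecord, dict]:
    """Overlay blood streaks / glare disks onto a record, keeping labels.

    Unlike cohort-spec artifacts, injected artifact pixels retain their
    underlying tissue labels — they stay in the labeled sample set, so blood
    over annotated non-malignant tissue produces exactly the false-positive
    pressure the blood filter is meant to relieve. Returns the modified record
    (a copy) and a truth map ``{"blood": bool HxW, "glare": bool HxW}`` of
    artifact positions for test assertions.
    """
    if blood_fraction < 0 or glare_fraction < 0 or blood_fraction + glare_fraction >= 1:
        raise ValueError("infeasible artifact fractions")
    h, w = record.cube.spatial_shape
    grid = record.cube.grid
    rng = _patient_rng(seed, record.patient_id + "/artifacts")
    out = record.copy()
    truth = {
        "blood": np.zeros((h, w), dtype=bool),
        "glare": np.zeros((h, w), dtype=bool),
    }
    if blood_fraction > 0:
        streaks = _blood_streaks(rng, h, w, int(round(blood_fraction * h * w)))
        blood = model.signature("blood", grid)
        noisy = blood + rng.normal(0.0, model.noise_sd, size=(int(streaks.sum()), len(grid)))
        out.cube.values[streaks] = np.clip(noisy, 0.0, None)
        truth["blood"] = streaks
    if glare_fraction > 0:
        disks = _glare_disks(rng, h, w, int(round(glare_fraction * h * w)))
        glare = model.signature("glare", grid)
        noisy = glare + rng.normal(0.0, model.noise_sd, size=(int(disks.sum()), len(grid)))
        out.cube.values[disks] = np.clip(noisy, 0.0, None)
        truth["glare"] = disks
    return out, truth


def true_blood_threshold(model: SpectralModel, grid: WavelengthGrid) -> float:
    """Midpoint between the tissue and blood 510-570 nm means — the generator's
    ground-truth blood-filter threshold (metric B separates at this value)."""
    win = grid.window(510.0, 570.0)
    b_blood = float(model.signature("blood", grid)[win].mean())
    b_tissue = max(
        float(model.signature("non_malignant", grid)[win].mean()),
        float(model.signature("cancer", grid)[win].mean()),
    )
    return 0.5 * (b_blood + b_tissue)


def true_light_threshold(model: SpectralModel, grid: WavelengthGrid) -> float:
    """Midpoint between the glare plateau and the dimmest tissue broadband mean."""
    a_glare = model.glare_level
    a_tissue = min(
        float(model.signature("non_malignant", grid).mean()),
        float(model.signature("cancer", grid).mean()),
    )
    return 0.5 * (a_glare + a_tissue)
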