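"""Per-cube preprocessing transforms and the combination grid.

A *preprocessing combination* is one point of the benchmark grid: scaling
(unit-length normalization or per-spectrum z-score standardization), smoothing
(median / Gaussian / Savitzky-Golay, applied spectrally (1D), spatially (2D) or
jointly (3D)), artifact filtering (light / blood thresholds on the band-window
metrics A and B), class-vs-sample weighting, and patch size. The pipeline
order is fixed and observable:

    metrics on raw full-band cube -> band exclusion (>= 540 nm) -> scaling
    -> smoothing -> exclusion mask applied to the labeled set -> patch
    extraction

Artifact metrics are computed on the raw full-band cube *before* the 500-540 nm
exclusion because metric B's 510-570 nm window overlaps the excluded range.

Scaling operates per pixel spectrum (not per band): unit-length divides each
spectrum by its Euclidean norm (92-band flat spectra land at 1/sqrt(92) ~ 0.104,
the "0 to 0.14" compressed range that makes normalization a weak choice);
z-score subtracts the spectrum mean and divides by its population sd, giving
the wider roughly [-3, 2] spread.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .hypercube_core import (
    Hypercube,
    HypercubeError,
    PatchSet,
    PatientRecord,
    WavelengthGrid,
    extract_patches,
    select_bands,
)

#: Default lower wavelength cut — bands below this are excluded as noisy.
BAND_EXCLUSION_MIN_NM = 540.0

SCALINGS = ("normalization", "standardization")
WEIGHTINGS = ("class", "sample")
SMOOTH_MODES = ("none", "d1", "d2", "d3")
SMOOTH_FILTERS = ("median", "gaussian", "savgol")


class CombinationError(ValueError):
    """Raised on constraint-violating smoothing/filtering/grid configs."""


@dataclass(frozen=True)
class SmoothingSpec:
    """One smoothing setting.

    ``mode`` is "none" (identity), "d1" (spectral, per pixel), "d2" (spatial,
    per band) or "d3" (joint). ``param`` is the odd window size for the median
    and Savitzky-Golay filters or the sigma for the Gaussian. Savitzky-Golay
    is spectral-only (mode "d1") with default window 9 / polynomial order 2.
    """

    mode: str = "none"
    filter: str = "median"
    param: float = 3
    savgol_order: int = 2

    def __post_init__(self):
        if self.mode not in SMOOTH_MODES:
            raise CombinationError(f"unknown smoothing mode {self.mode!r}")
        if self.mode == "none":
            return
        if self.filter not in SMOOTH_FILTERS:
            raise CombinationError(f"unknown smoothing filter {self.filter!r}")
        if self.param <= 0:
            raise CombinationError("smoothing param must be positive")
        if self.filter in ("median", "savgol"):
            if int(self.param) != self.param or int(self.param) % 2 != 1:
                raise CombinationError(
                    f"{self.filter} window must be an odd integer, got {self.param}"
                )
        if self.filter == "savgol":
            if self.mode != "d1":
                raise CombinationError("Savitzky-Golay smoothing is spectral-only (mode d1)")
            if self.param <= self.savgol_order:
                raise CombinationError("Savitzky-Golay window must exceed its order")

    def describe(self) -> str:
        if self.mode == "none":
            return "none"
        return f"{self.mode}-{self.filter}-{self.param:g}"


@dataclass(frozen=True)
class FilterSpec:
    """Light/blood artifact filtering thresholds (None disables a predicate).

    The light predicate flags pixels whose broadband mean A falls *below* the
    light threshold; the blood predicate flags pixels whose 510-570 nm mean B
    rises *above* the blood threshold. ``use_c_conjunct`` additionally requires
    metric C < 0 (the original background-extraction algorithm's three-way
    conjunction) for a pixel to be excluded.
    """

    light_threshold: float | None = None
    blood_threshold: float | None = None
    use_c_conjunct: bool = False
    c_constant: float = 0.1

    def __post_init__(self):
        for name in ("light_threshold", "blood_threshold"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise CombinationError(f"{name}={v} outside (0, 1)")
        if self.c_constant <= 0:
            raise CombinationError("c_constant must be positive")

    def describe(self) -> tuple[str, str]:
        lt = "none" if self.light_threshold is None else f"{self.light_threshold:g}"
        bt = "none" if self.blood_threshold is None else f"{self.blood_threshold:g}"
        return lt, bt


@dataclass(frozen=True)
class PreprocessingCombination:
    """One point of the experiment grid."""

    scaling: str = "standardization"
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    filtering: FilterSpec = field(default_factory=FilterSpec)
    weighting: str = "sample"
    patch_size: int = 3

    def __post_init__(self):
        if self.scaling not in SCALINGS:
            raise CombinationError(f"unknown scaling {self.scaling!r}")
        if self.weighting not in WEIGHTINGS:
            raise CombinationError(f"unknown weighting {self.weighting!r}")
        if self.patch_size % 2 != 1 or self.patch_size < 1:
            raise CombinationError(f"patch_size must be a positive odd int, got {self.patch_size}")

    def as_record(self) -> dict:
        """Flat key=value serialization for results tables."""
        lt, bt = self.filtering.describe()
        return {
            "scaling": self.scaling,
            "smoothing_mode": self.smoothing.mode if self.smoothing.mode != "none" else "none",
            "smoothing_filter": self.smoothing.filter if self.smoothing.mode != "none" else "none",
            "smoothing_param": f"{self.smoothing.param:g}" if self.smoothing.mode != "none" else "none",
            "light_threshold": lt,
            "blood_threshold": bt,
            "weighting": self.weighting,
            "patch_size": self.patch_size,
        }


@dataclass
class ArtifactMetrics:
    """Per-pixel band-window statistics computed on the raw full-band cube.

    A: mean reflectance over 500-1000 nm (broadband); B: mean over 510-570 nm
    (the hemoglobin-dominated green window); C: ln(mean over 650-710 nm
    divided by ``c_constant``).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    c_constant: float


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def scale_unit_length(cube: Hypercube) -> Hypercube:
    """Divide each pixel spectrum by its Euclidean (L2) norm."""
    norms = np.linalg.norm(cube.values, axis=2)
    if np.any(norms == 0):
        r, c = np.argwhere(norms == 0)[0]
        raise HypercubeError(f"zero spectrum at pixel ({r}, {c}) cannot be unit-scaled")
    return Hypercube(cube.values / norms[:, :, None], cube.grid)


def scale_zscore(cube: Hypercube) -> Hypercube:
    """Per pixel spectrum: subtract the mean, divide by the population sd."""
    mean = cube.values.mean(axis=2)
    sd = cube.values.std(axis=2)  # population sd (ddof=0)
    if np.any(sd == 0):
        r, c = np.argwhere(sd == 0)[0]
        raise HypercubeError(f"constant spectrum at pixel ({r}, {c}) cannot be standardized")
    return Hypercube((cube.values - mean[:, :, None]) / sd[:, :, None], cube.grid)


_SCALERS = {"normalization": scale_unit_length, "standardization": scale_zscore}


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth(cube: Hypercube, spec: SmoothingSpec) -> Hypercube:
    """Apply ``spec`` to the cube; shape is always preserved.

    Axis semantics: d1 smooths along the band axis independently per pixel,
    d2 smooths each band's spatial plane, d3 smooths all three axes jointly.
    Median and Gaussian edges use replicate (nearest) padding; Savitzky-Golay
    uses its nearest-interpolation edge mode.
    """
    if spec.mode == "none":
        return cube
    axes = {"d1": (2,), "d2": (0, 1), "d3": (0, 1, 2)}[spec.mode]
    v = cube.values
    if spec.filter == "median":
        w = int(spec.param)
        for ax in axes:
            if w > v.shape[ax]:
                raise CombinationError(
                    f"median window {w} exceeds axis {ax} length {v.shape[ax]}"
                )
        size = tuple(int(spec.param) if ax in axes else 1 for ax in range(3))
        out = ndimage.median_filter(v, size=size, mode="nearest")
    elif spec.filter == "gaussian":
        sigma = tuple(float(spec.param) if ax in axes else 0.0 for ax in range(3))
        out = ndimage.gaussian_filter(v, sigma=sigma, mode="nearest")
    else:  # savgol, d1 only (validated at construction)
        w = int(spec.param)
        if w > v.shape[2]:
            raise CombinationError(f"Savitzky-Golay window {w} exceeds band count {v.shape[2]}")
        out = signal.savgol_filter(v, window_length=w, polyorder=spec.savgol_order,
                                   axis=2, mode="nearest")
    return Hypercube(out, cube.grid)


# ---------------------------------------------------------------------------
# Artifact metrics and exclusion
# ---------------------------------------------------------------------------

def artifact_metrics(cube: Hypercube, c_constant: float = 0.1) -> ArtifactMetrics:
    """Compute metrics A, B, C on the (raw, full-band) cube.

    Band windows are inclusive on both ends; an empty window is an error
    (e.g. computing B on an already band-excluded cube missing 510-540 nm
    would silently change its meaning, so the full-band cube is required
    upstream).
    """
    windows = {"A": (500.0, 1000.0), "B": (510.0, 570.0), "C": (650.0, 710.0)}
    means = {}
    for name, (lo, hi) in windows.items():
        idx = cube.grid.window(lo, hi)
        if idx.size == 0:
            raise HypercubeError(f"metric {name} window {lo}-{hi} nm absent from grid")
        means[name] = cube.values[:, :, idx].mean(axis=2)
    with np.errstate(divide="ignore"):
        c_metric = np.log(means["C"] / c_constant)
    return ArtifactMetrics(A=means["A"], B=means["B"], C=c_metric, c_constant=c_constant)


def exclusion_mask(metrics: ArtifactMetrics, spec: FilterSpec) -> np.ndarray:
    """Boolean H x W mask of pixels excluded from the labeled sample set.

    Light mask: A < light_threshold (dim pixels); blood mask: B >
    blood_threshold. Each enabled predicate is optionally conjoined with
    C < 0; the final exclusion is the union of the enabled masks.
    """
    shape = metrics.A.shape
    excluded = np.zeros(shape, dtype=bool)
    c_neg = metrics.C < 0
    if spec.light_threshold is not None:
        light = metrics.A < spec.light_threshold
        if spec.use_c_conjunct:
            light &= c_neg
        excluded |= light
    if spec.blood_threshold is not None:
        blood = metrics.B > spec.blood_threshold
        if spec.use_c_conjunct:
            blood &= c_neg
        excluded |= blood
    return excluded


# ---------------------------------------------------------------------------
# Pipeline assembly
# ---------------------------------------------------------------------------

def apply_combination(
    record: PatientRecord,
    combo: PreprocessingCombination,
    pixels: np.ndarray | None = None,
    min_nm: float = BAND_EXCLUSION_MIN_NM,
    trace: list | None = None,
) -> PatchSet:
    """Run the full per-patient pipeline for one combination.

    ``record`` must hold the raw full-band cube. ``pixels`` optionally
    restricts (and orders) the labeled pixels considered, e.g. a
    representative-subset draw; excluded pixels are removed while the relative
    order of survivors is preserved, so the delivered sample order is
    identical across combinations by pixel identity. ``trace``, if given, is
    appended with stage names as they execute.
    """
    def log(stage: str):
        if trace is not None:
            trace.append(stage)

    metrics = artifact_metrics(record.cube, c_constant=combo.filtering.c_constant)
    log("artifact_metrics")
    cube = select_bands(record.cube, min_nm)
    log("band_exclusion")
    cube = _SCALERS[combo.scaling](cube)
    log(f"scaling:{combo.scaling}")
    cube = smooth(cube, combo.smoothing)
    log(f"smoothing:{combo.smoothing.describe()}")
    excluded = exclusion_mask(metrics, combo.filtering)
    if pixels is None:
        pixels = record.mask.sample_pixels()
    else:
        pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
    keep = ~excluded[pixels[:, 0], pixels[:, 1]]
    pixels = pixels[keep]
    log("exclusion_mask")
    patch_record = PatientRecord(record.patient_id, cube, record.mask)
    patches = extract_patches(patch_record, combo.patch_size, pixels=pixels)
    log("patch_extraction")
    return patches


# ---------------------------------------------------------------------------
# Grid enumeration
# ---------------------------------------------------------------------------

def default_grid_config() -> dict:
    """The benchmark grid config with the parameter values named in the text."""
    return {
        "scaling": list(SCALINGS),
        "weighting": list(WEIGHTINGS),
        "patch_size": [3, 5],
        "smoothing": {
            "include_none": True,
            "median": {"modes": ["d1", "d2", "d3"], "params": [3, 5, 7]},
            "gaussian": {"modes": ["d1", "d2", "d3"], "params": [0.5, 1.5, 2]},
            "savgol": {"modes": ["d1"], "params": [9], "order": 2},
        },
        "filtering": {
            "include_none": True,
            "light_thresholds": [0.25, 0.7],
            "blood_thresholds": [0.1, 0.15],
        },
    }


def _smoothing_options(cfg: dict) -> list[SmoothingSpec]:
    opts: list[SmoothingSpec] = []
    if cfg.get("include_none", True):
        opts.append(SmoothingSpec(mode="none"))
    for filt in ("median", "gaussian", "savgol"):
        sub = cfg.get(filt)
        if not sub:
            continue
        order = int(sub.get("order", 2))
        for mode in sub["modes"]:
            for param in sub["params"]:
                # constraint violations (e.g. savgol listed under d2) raise here
                opts.append(
                    SmoothingSpec(mode=mode, filter=filt, param=param, savgol_order=order)
                )
    return opts


def _filtering_options(cfg: dict) -> list[FilterSpec]:
    lights = [None] + list(cfg.get("light_thresholds", []))
    bloods = [None] + list(cfg.get("blood_thresholds", []))
    use_c = bool(cfg.get("use_c_conjunct", False))
    c_const = float(cfg.get("c_constant", 0.1))
    opts = [
        FilterSpec(light_threshold=lt, blood_threshold=bt,
                   use_c_conjunct=use_c, c_constant=c_const)
        for lt, bt in itertools.product(lights, bloods)
    ]
    if not cfg.get("include_none", True):
        opts = [o for o in opts if not (o.light_threshold is None and o.blood_threshold is None)]
    return opts


def enumerate_grid(grid_config: dict | None = None) -> list[PreprocessingCombination]:
    """Cartesian product of the configured factor levels, constraint-checked.

    Order is deterministic and documented: patch_size, scaling, weighting,
    smoothing (none first, then median/gaussian/savgol by mode then param),
    filtering (light outer, blood inner, none first) — nested loops in that
    order, so runs of the same config are always comparable row-by-row.
    """
    cfg = grid_config if grid_config is not None else default_grid_config()
    smoothings = _smoothing_options(cfg.get("smoothing", {"include_none": True}))
    filterings = _filtering_options(cfg.get("filtering", {"include_none": True}))
    combos = [
        PreprocessingCombination(
            scaling=sc, smoothing=sm, filtering=fl, weighting=wt, patch_size=ps
        )
        for ps in cfg.get("patch_size", [3])
        for sc in cfg.get("scaling", ["standardization"])
        for wt in cfg.get("weighting", ["sample"])
        for sm in smoothings
        for fl in filterings
    ]
    return combos
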