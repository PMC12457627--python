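"""Data model and I/O for hyperspectral cubes and annotation masks.

A *hypercube* is a reflectance volume of shape (H, W, B): two spatial axes and
one spectral axis whose band centers are carried by a :class:`WavelengthGrid`.
Pixels carry ground-truth labels in a companion :class:`AnnotationMask`; only
``NON_MALIGNANT`` and ``CANCER`` pixels ever become training or evaluation
samples, while ``MARGIN`` and ``UNLABELED`` pixels are excluded from both (they
still participate in artifact filtering, which operates on the raw cube).

Cubes are stored on disk as ENVI-style rasters: a plain-text ``.hdr`` file
holding geometry and the wavelength list, next to a little-endian 32-bit float
band-sequential (BSQ) binary. Masks are stored either as indexed PNG images
using the palette below, or as ``row,col,label`` CSV.

Label palette (indexed-PNG values):

====================  =====
label                 index
====================  =====
``NON_MALIGNANT``     0
``CANCER``            1
``MARGIN``            2
``UNLABELED``         255
====================  =====

Coordinates are 0-based ``(row, col)``, row-major; bands are indexed by their
position in the wavelength grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

NON_MALIGNANT = 0
CANCER = 1
MARGIN = 2
UNLABELED = 255

#: Labels that yield samples (training and evaluation).
SAMPLE_LABELS = (NON_MALIGNANT, CANCER)

LABEL_NAMES = {
    NON_MALIGNANT: "non_malignant",
    CANCER: "cancer",
    MARGIN: "margin",
    UNLABELED: "unlabeled",
}

# Display palette for indexed-PNG masks: purple / yellow / red / black.
_MASK_PALETTE = {
    NON_MALIGNANT: (128, 0, 160),
    CANCER: (255, 220, 0),
    MARGIN: (220, 30, 30),
    UNLABELED: (0, 0, 0),
}


class HypercubeError(ValueError):
    """Raised on malformed cubes, masks, or on cube/mask misalignment."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    centers_nm: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers_nm, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise HypercubeError("wavelength grid must be a nonempty 1-D sequence")
        if not np.all(np.diff(centers) > 0):
            raise HypercubeError("wavelength centers must be strictly increasing")
        object.__setattr__(self, "centers_nm", centers)

    @classmethod
    def from_range(cls, start_nm: float, stop_nm: float, step_nm: float) -> "WavelengthGrid":
        """Uniform grid from ``start_nm`` to ``stop_nm`` inclusive."""
        n = int(round((stop_nm - start_nm) / step_nm)) + 1
        return cls(start_nm + step_nm * np.arange(n))

    def __len__(self) -> int:
        return int(self.centers_nm.size)

    def window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands with center in [lo_nm, hi_nm], inclusive on both ends."""
        c = self.centers_nm
        return np.nonzero((c >= lo_nm) & (c <= hi_nm))[0]


@dataclass
class Hypercube:
    """Reflectance volume (H, W, B) plus its wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise HypercubeError(f"cube must be 3-D (H, W, B), got shape {self.values.shape}")
        if self.values.shape[2] != len(self.grid):
            raise HypercubeError(
                f"cube has {self.values.shape[2]} bands but grid has {len(self.grid)} centers"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def copy(self) -> "Hypercube":
        return Hypercube(self.values.copy(), self.grid)


@dataclass
class AnnotationMask:
    """Per-pixel label image aligned to a cube."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise HypercubeError("mask must be 2-D (H, W)")
        valid = set(LABEL_NAMES)
        found = set(np.unique(labels).tolist())
        if not found <= valid:
            raise HypercubeError(f"mask contains invalid labels {sorted(found - valid)}")
        self.labels = labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def sample_pixels(self) -> np.ndarray:
        """(n, 2) array of (row, col) for labeled sample pixels, row-major order."""
        rows, cols = np.nonzero(np.isin(self.labels, SAMPLE_LABELS))
        return np.stack([rows, cols], axis=1)

    def copy(self) -> "AnnotationMask":
        return AnnotationMask(self.labels.copy())


@dataclass
class PatientRecord:
    """One patient's cube plus its aligned ground-truth mask."""

    patient_id: str
    cube: Hypercube
    mask: AnnotationMask

    def __post_init__(self):
        if self.cube.spatial_shape != self.mask.shape:
            raise HypercubeError(
                f"patient {self.patient_id!r}: cube spatial shape "
                f"{self.cube.spatial_shape} != mask shape {self.mask.shape}"
            )

    def copy(self) -> "PatientRecord":
        return PatientRecord(self.patient_id, self.cube.copy(), self.mask.copy())


@dataclass
class PatchSet:
    """Per-pixel 3-D patches with parallel labels and coordinates.

    ``patches`` has shape (n, patch_size, patch_size, B); ``labels`` is a
    binary vector (1 = cancer); ``pixel_coords`` holds the (row, col) of each
    patch center in the source cube.
    """

    patches: np.ndarray
    labels: np.ndarray
    pixel_coords: np.ndarray
    patient_id: str

    def __post_init__(self):
        n = self.patches.shape[0]
        if not (self.labels.shape == (n,) and self.pixel_coords.shape == (n, 2)):
            raise HypercubeError("patches, labels, pixel_coords lengths differ")

    def __len__(self) -> int:
        return int(self.patches.shape[0])


# ---------------------------------------------------------------------------
# ENVI-style cube I/O
# ---------------------------------------------------------------------------

def write_cube(cube: Hypercube, path: Path) -> None:
    """Write ``cube`` as ENVI-style ``path``(+``.hdr``): float32 LE, BSQ."""
    path = Path(path)
    h, w, b = cube.shape
    wl = ", ".join(f"{c:g}" for c in cube.grid.centers_nm)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)
    cube.values.transpose(2, 0, 1).astype("<f4").tofile(path)


def _parse_envi_header(text: str) -> dict:
    # ENVI headers are "key = value" lines; {...} values may span lines.
    if not text.lstrip().startswith("ENVI"):
        raise HypercubeError("missing ENVI magic in header")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq < 0:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1 :]
        if rest.lstrip().startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise HypercubeError("unterminated { } value in ENVI header")
            value = rest[: close + 1]
            i = eq + 1 + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl]
            i = eq + 1 + nl + 1
        if key:
            fields[key] = value.strip()
    return fields


def read_cube(path: Path) -> Hypercube:
    """Read an ENVI-style cube written by :func:`write_cube`."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise HypercubeError(f"missing header file {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        wl_raw = fields["wavelength"].strip("{} \n")
    except KeyError as exc:
        raise HypercubeError(f"ENVI header missing required field {exc}") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise HypercubeError("only BSQ interleave is supported")
    if fields.get("data type", "4") != "4":
        raise HypercubeError("only data type 4 (float32) is supported")
    centers = np.array([float(tok) for tok in wl_raw.split(",") if tok.strip()])
    if centers.size != b:
        raise HypercubeError(f"header lists {centers.size} wavelengths for {b} bands")
    raw = np.fromfile(path, dtype="<f4")
    if raw.size != h * w * b:
        raise HypercubeError(f"raster size {raw.size} != lines*samples*bands {h * w * b}")
    values = raw.reshape(b, h, w).transpose(1, 2, 0)
    return Hypercube(values, WavelengthGrid(centers))


# ---------------------------------------------------------------------------
# Mask I/O (indexed PNG or CSV)
# ---------------------------------------------------------------------------

def write_mask(mask: AnnotationMask, path: Path) -> None:
    """Write ``mask`` as an indexed PNG (``.png``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        img = Image.fromarray(mask.labels, mode="P")
        palette = [0] * (256 * 3)
        for idx, rgb in _MASK_PALETTE.items():
            palette[3 * idx : 3 * idx + 3] = rgb
        img.putpalette(palette)
        img.save(path)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "label"])
            for (r, c), lab in np.ndenumerate(mask.labels):
                writer.writerow([r, c, int(lab)])


def read_mask(path: Path, shape: tuple[int, int] | None = None) -> AnnotationMask:
    """Read a mask written by :func:`write_mask`.

    ``shape`` is required for CSV masks (the CSV stores sparse coordinates).
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        img = Image.open(path)
        labels = np.asarray(img, dtype=np.uint8)
        return AnnotationMask(labels)
    if shape is None:
        raise HypercubeError("shape is required to read a CSV mask")
    labels = np.full(shape, UNLABELED, dtype=np.uint8)
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            labels[int(rec["row"]), int(rec["col"])] = int(rec["label"])
    return AnnotationMask(labels)


def write_patient(record: PatientRecord, cube_path: Path, mask_path: Path) -> None:
    write_cube(record.cube, cube_path)
    write_mask(record.mask, mask_path)


def read_patient(cube_path: Path, mask_path: Path, patient_id: str | None = None) -> PatientRecord:
    """Read an aligned cube + mask pair; errors on dimension mismatch."""
    cube = read_cube(cube_path)
    mask = read_mask(mask_path, shape=cube.spatial_shape)
    pid = patient_id if patient_id is not None else Path(cube_path).stem
    return PatientRecord(pid, cube, mask)


# ---------------------------------------------------------------------------
# Band selection, label accounting, patch extraction
# ---------------------------------------------------------------------------

def select_bands(cube: Hypercube, min_nm: float) -> Hypercube:
    """Restrict ``cube`` to bands with center >= ``min_nm`` (order preserved).

    The study discards the noisy 500-540 nm range, retaining 92 of 100 bands;
    ``min_nm`` equal to the first center is a no-op.
    """
    keep = cube.grid.centers_nm >= min_nm
    if not keep.any():
        raise HypercubeError(f"min_nm={min_nm} excludes every band")
    if keep.all():
        return cube
    return Hypercube(cube.values[:, :, keep], WavelengthGrid(cube.grid.centers_nm[keep]))


def label_counts(records: list[PatientRecord]) -> pd.DataFrame:
    """Exact per-patient, per-class pixel counts plus a cohort ``total`` row.

    Columns are the four label names; sample classes (non-malignant, cancer)
    are reported separately from margin/unlabeled, which never count toward
    class totals.
    """
    rows = {}
    for rec in records:
        labs = rec.mask.labels
        rows[rec.patient_id] = {
            name: int(np.count_nonzero(labs == code)) for code, name in LABEL_NAMES.items()
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.loc["total"] = frame.sum(axis=0)
    frame.index.name = "patient_id"
    return frame


def extract_patches(
    record: PatientRecord,
    patch_size: int,
    pixels: np.ndarray | None = None,
) -> PatchSet:
    """Extract one (patch_size, patch_size, B) patch per labeled sample pixel.

    Each patch is centered on its pixel; spatial borders are reflect-padded
    (mirror, edge value not repeated) so corner and edge pixels still yield
    full patches. ``pixels`` optionally restricts extraction to the given
    (row, col) list, in the given order — used to deliver identical sample
    orders across preprocessing combinations. Pixels whose label is not a
    sample class are silently skipped.
    """
    if patch_size % 2 != 1:
        raise HypercubeError(f"patch_size must be odd, got {patch_size}")
    h, w, b = record.cube.shape
    if patch_size > 2 * min(h, w):
        raise HypercubeError(f"patch_size {patch_size} too large for {h}x{w} cube")
    half = patch_size // 2
    padded = np.pad(record.cube.values, ((half, half), (half, half), (0, 0)), mode="reflect")
    if pixels is None:
        pixels = record.mask.sample_pixels()
    else:
        pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
        keep = np.isin(record.mask.labels[pixels[:, 0], pixels[:, 1]], SAMPLE_LABELS)
        pixels = pixels[keep]
    n = pixels.shape[0]
    patches = np.empty((n, patch_size, patch_size, b), dtype=record.cube.values.dtype)
    for i, (r, c) in enumerate(pixels):
        patches[i] = padded[r : r + patch_size, c : c + patch_size, :]
    labels = (record.mask.labels[pixels[:, 0], pixels[:, 1]] == CANCER).astype(np.int8)
    return PatchSet(patches, labels, pixels.copy(), record.patient_id)
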