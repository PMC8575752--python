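"""Polar IVUS pullback containers, portable on-disk formats, and
pullback eligibility/selection rules.

A pullback is a stack of polar frames: ``frames[frame][aline][sample]``,
8-bit grayscale, where each row of a frame is one A-line (a radial scan
line) and each column a radial depth sample.  The native on-disk format
is a multi-frame grayscale TIFF plus a JSON metadata sidecar
``<name>.meta.json``; per-A-line annotation masks are headerless CSV
grids of 0/1 (``n_frames`` rows x ``n_alines`` columns) named
``<name>.mask.csv``.

Eligibility follows the clinical inclusion rules: a motorized pullback
must cover >= 40 mm of vessel (boundary inclusive) and be free of stent
struts, poor image quality, and false-lumen catheter positions.  When a
patient has several analyzable pullbacks, the longest eligible one is
the study pullback.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
from scipy import ndimage

from .score import compute_ics  # noqa: F401  (re-exported convenience)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

VESSEL_LABELS = ("LAD", "LCX", "RCA", "LM", "synthetic")
MASK_SOURCES = ("ground_truth", "manual", "svm", "rule_based")

#: Minimum analyzable pullback length in mm (inclusive boundary).
MIN_LENGTH_MM = 40.0


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata of a motorized IVUS pullback.

    Defaults describe a 40 MHz mechanically rotating catheter pulled
    back at 0.5 mm/s; frame rate and sampling grid are typical values
    for such systems.
    """

    pullback_speed_mm_s: float = 0.5
    frame_rate_hz: float = 30.0
    transducer_freq_mhz: float = 40.0
    n_alines: int = 256
    n_samples: int = 512
    radial_extent_mm: float = 4.5

    def __post_init__(self) -> None:
        for name in ("pullback_speed_mm_s", "frame_rate_hz",
                     "transducer_freq_mhz", "radial_extent_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_alines", "n_samples"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 8):
                raise ValueError(f"{name} must be an integer >= 8")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class QualityFlags:
    """Operator-assessed exclusion flags (metadata, never computed)."""

    has_stent_struts: bool = False
    poor_quality: bool = False
    catheter_in_false_lumen: bool = False

    def any(self) -> bool:
        return self.has_stent_struts or self.poor_quality or self.catheter_in_false_lumen

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Pullback:
    """A polar-domain IVUS pullback: intensity grid + metadata."""

    frames: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    flags: QualityFlags = field(default_factory=QualityFlags)
    vessel_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, aline, sample) grid")
        if self.frames.dtype != np.uint8:
            if self.frames.min(initial=0) < 0 or self.frames.max(initial=0) > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        n_frames, n_alines, n_samples = self.frames.shape
        if (n_alines, n_samples) != (self.meta.n_alines, self.meta.n_samples):
            raise ValueError(
                f"frame grid {n_alines}x{n_samples} inconsistent with metadata "
                f"{self.meta.n_alines}x{self.meta.n_samples}"
            )
        if self.vessel_label not in VESSEL_LABELS:
            raise ValueError(f"vessel_label must be one of {VESSEL_LABELS}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AnnotationMask:
    """Per-(frame, A-line) boolean calcium labels."""

    mask: np.ndarray
    source: str = "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (frame, aline)")
        if self.source not in MASK_SOURCES:
            raise ValueError(f"source must be one of {MASK_SOURCES}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    reasons: Tuple[str, ...]


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def meta_sidecar_path(path: PathLike) -> Path:
    """``x.tif`` -> ``x.meta.json`` (sidecar naming convention)."""
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def write_pullback(pullback: Pullback, path: PathLike) -> None:
    """Write a pullback as a multi-frame 8-bit TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, pullback.frames, photometric="minisblack")
    sidecar = {
        **pullback.meta.to_dict(),
        "flags": pullback.flags.to_dict(),
        "vessel_label": pullback.vessel_label,
    }
    meta_sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_pullback(path: PathLike, meta_path: Optional[PathLike] = None) -> Pullback:
    """Read a pullback from a multi-frame TIFF stack + JSON sidecar.

    Metadata fields missing from the sidecar are filled with
    :class:`AcquisitionMeta` defaults (with a logged warning).  Grid
    dimensions always come from the stack itself.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3 or frames.dtype == object:
        raise ValueError(f"{path}: inconsistent frame dimensions across stack")

    meta_path = Path(meta_path) if meta_path is not None else meta_sidecar_path(path)
    raw: dict = {}
    if meta_path.exists():
        raw = json.loads(meta_path.read_text())
    else:
        log.warning("no metadata sidecar at %s; using acquisition defaults", meta_path)

    defaults = AcquisitionMeta()
    kwargs = {}
    for f in dataclasses.fields(AcquisitionMeta):
        if f.name in ("n_alines", "n_samples"):
            continue  # taken from the stack below
        if f.name in raw:
            kwargs[f.name] = raw[f.name]
        else:
            kwargs[f.name] = getattr(defaults, f.name)
            if raw:
                log.warning("sidecar %s lacks %s; using default %r",
                            meta_path.name, f.name, kwargs[f.name])
    n_frames, n_alines, n_samples = frames.shape
    for key, actual in (("n_alines", n_alines), ("n_samples", n_samples)):
        if key in raw and int(raw[key]) != actual:
            log.warning("sidecar %s says %s=%s but stack has %d; using the stack",
                        meta_path.name, key, raw[key], actual)
    meta = AcquisitionMeta(n_alines=n_alines, n_samples=n_samples, **kwargs)

    flags = QualityFlags(**raw.get("flags", {}))
    vessel = raw.get("vessel_label", "synthetic")
    return Pullback(frames=frames, meta=meta, flags=flags, vessel_label=vessel)


def write_mask(mask: AnnotationMask, path: PathLike) -> None:
    """Write a mask as a headerless CSV of 0/1 (frames x A-lines)."""
    np.savetxt(path, mask.mask.astype(np.uint8), fmt="%d", delimiter=",")


def read_mask(path: PathLike, source: str = "manual") -> AnnotationMask:
    arr = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return AnnotationMask(mask=arr.astype(bool), source=source)


def read_dicom_frames(path: PathLike) -> np.ndarray:
    """Extract grayscale frames from a (multi-frame) DICOM file.

    Only pixel extraction is supported: color frames are collapsed to
    luminance by channel averaging and rescaled to 8 bit.  Vendor-specific
    IVUS payloads beyond the standard pixel data are ignored.
    """
    import pydicom  # optional dependency

    ds = pydicom.dcmread(str(path))
    arr = np.asarray(ds.pixel_array)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        arr = arr[np.newaxis, ..., :3].mean(axis=-1)
    arr = arr.astype(float)
    hi = arr.max()
    if hi > 255:
        arr = arr * (255.0 / hi)
    return np.clip(arr, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def cartesian_to_polar(frame: np.ndarray, center: Tuple[float, float],
                       n_alines: int, n_samples: int) -> np.ndarray:
    """Resample a Cartesian (scan-converted) frame onto a polar grid.

    Rows of the result are A-lines at uniformly spaced angles in
    [0, 2*pi); columns are radial samples at 1-pixel spacing from
    ``center`` outward.  Bilinear interpolation; samples falling outside
    the image are 0.  ``center`` is (row, col) in pixel coordinates.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    cy, cx = float(center[0]), float(center[1])
    h, w = frame.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("center must lie inside the image")
    theta = 2.0 * np.pi * np.arange(n_alines) / n_alines
    r = np.arange(n_samples, dtype=float)
    rows = cy + np.outer(np.sin(theta), r)
    cols = cx + np.outer(np.cos(theta), r)
    polar = ndimage.map_coordinates(frame, [rows, cols], order=1,
                                    mode="constant", cval=0.0)
    return polar


# ---------------------------------------------------------------------------
# eligibility and selection
# ---------------------------------------------------------------------------

def pullback_length_mm(pullback: Pullback) -> float:
    """Imaged vessel length: n_frames / frame_rate * pullback_speed."""
    m = pullback.meta
    return pullback.n_frames / m.frame_rate_hz * m.pullback_speed_mm_s


def check_eligibility(pullback: Pullback) -> EligibilityVerdict:
    """Apply the study inclusion rules to one pullback.

    Eligible iff the pullback covers >= 40 mm (inclusive) and none of
    the three exclusion flags is set.  ``reasons`` lists every failed
    criterion.
    """
    reasons: List[str] = []
    if pullback_length_mm(pullback) < MIN_LENGTH_MM:
        reasons.append("length < 40 mm")
    if pullback.flags.has_stent_struts:
        reasons.append("stent struts")
    if pullback.flags.poor_quality:
        reasons.append("poor image quality")
    if pullback.flags.catheter_in_false_lumen:
        reasons.append("catheter in false lumen")
    return EligibilityVerdict(eligible=not reasons, reasons=tuple(reasons))


def select_study_pullback(pullbacks: Sequence[Pullback]) -> Optional[Pullback]:
    """Pick the study pullback: the longest eligible one.

    Returns ``None`` when no pullback is eligible.  Ties in length are
    broken by input order (first wins).
    """
    best: Optional[Pullback] = None
    best_len = -np.inf
    for pb in pullbacks:
        if not check_eligibility(pb).eligible:
            continue
        length = pullback_length_mm(pb)
        if length > best_len:
            best, best_len = pb, length
    return best
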