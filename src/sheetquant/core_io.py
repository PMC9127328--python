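"""Data model and file I/O for the membrane-sheet analysis pipeline.

Conventions used throughout the package:

* image coordinates are 0-based ``(row, col)`` pixel indices; rectangles are
  half-open (``row0 <= r < row0 + height``),
* physical positions and distances are reported in nanometres via the
  micrograph's ``pixel_size_nm``,
* multi-channel recordings are stored as separate :class:`Micrograph` objects
  sharing the same pixel grid; every two-channel operation checks that the
  grids match (equal shape and pixel size).

All downstream modules consume only the types defined here; no analysis
operation reads files directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon as _sk_polygon

ROI_ROLES = ("membrane", "background", "bleach", "reference")


@dataclass(frozen=True)
class Micrograph:
    """A single-channel 2D fluorescence image with physical pixel size.

    Parameters
    ----------
    pixels:
        2D array of non-negative, finite intensities (arbitrary units,
        detector counts taken as given).
    pixel_size_nm:
        Edge length of one pixel in nanometres (25 nm for the STED/confocal
        recordings, 64.5 nm for epifluorescence).
    channel:
        Free-text channel label, e.g. ``"APP-GFP"`` or ``"ADAM10"``.
    condition:
        Free-text experimental condition, e.g. ``"fixed"``, ``"control"``,
        ``"CoP"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"micrograph must be 2D, got shape {px.shape}")
        if min(px.shape) < 16:
            raise ValueError(f"micrograph must be at least 16x16, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("micrograph intensities must be finite")
        if np.any(px < 0):
            raise ValueError("micrograph intensities must be non-negative")
        if not (np.isfinite(self.pixel_size_nm) and self.pixel_size_nm > 0):
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def same_grid(self, other: "Micrograph") -> bool:
        """True if the two micrographs share shape and pixel size (registration check)."""
        return self.shape == other.shape and np.isclose(
            self.pixel_size_nm, other.pixel_size_nm
        )

    def flipped(self) -> "Micrograph":
        """Image flipped vertically and horizontally (180-degree rotation)."""
        return replace(self, pixels=self.pixels[::-1, ::-1].copy())


def require_same_grid(a: Micrograph, b: Micrograph) -> None:
    if not a.same_grid(b):
        raise ValueError(
            "two-channel operation requires matching pixel grids: "
            f"{a.shape}@{a.pixel_size_nm}nm vs {b.shape}@{b.pixel_size_nm}nm"
        )


@dataclass(frozen=True)
class Roi:
    """A rectangular or polygonal region of interest.

    ``rect`` is ``(row0, col0, height, width)`` in pixels, 0-based and
    half-open.  ``vertices`` is a sequence of ``(row, col)`` pairs (may be
    fractional).  Exactly one of the two must be given.  ``role`` records
    what the region is used for in an analysis.
    """

    rect: tuple[int, int, int, int] | None = None
    vertices: tuple[tuple[float, float], ...] | None = None
    role: str = "membrane"
    name: str = ""

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.vertices is None):
            raise ValueError("Roi needs exactly one of rect or vertices")
        if self.role not in ROI_ROLES:
            raise ValueError(f"Roi role must be one of {ROI_ROLES}, got {self.role!r}")
        if self.rect is not None:
            r0, c0, h, w = self.rect
            if h < 1 or w < 1:
                raise ValueError(f"rectangle ROI must have area >= 1 px, got {self.rect}")
            object.__setattr__(self, "rect", (int(r0), int(c0), int(h), int(w)))
        else:
            verts = tuple((float(r), float(c)) for r, c in self.vertices)
            if len(verts) < 3:
                raise ValueError("polygon ROI needs at least 3 vertices")
            object.__setattr__(self, "vertices", verts)

    @property
    def is_rect(self) -> bool:
        return self.rect is not None

    def bounds(self) -> tuple[float, float, float, float]:
        """(row_min, col_min, row_max, col_max); half-open for rectangles."""
        if self.rect is not None:
            r0, c0, h, w = self.rect
            return (r0, c0, r0 + h, c0 + w)
        rows = [v[0] for v in self.vertices]
        cols = [v[1] for v in self.vertices]
        return (min(rows), min(cols), max(rows) + 1, max(cols) + 1)

    def validate_inside(self, shape: tuple[int, int]) -> None:
        r0, c0, r1, c1 = self.bounds()
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError(
                f"ROI {self.name or self.role} with bounds {self.bounds()} "
                f"exceeds image shape {shape}"
            )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of the ROI on an image of the given shape."""
        self.validate_inside(shape)
        m = np.zeros(shape, dtype=bool)
        if self.rect is not None:
            r0, c0, h, w = self.rect
            m[r0 : r0 + h, c0 : c0 + w] = True
        else:
            rows = np.array([v[0] for v in self.vertices])
            cols = np.array([v[1] for v in self.vertices])
            rr, cc = _sk_polygon(rows, cols, shape=shape)
            m[rr, cc] = True
        if not m.any():
            raise ValueError(f"ROI {self.name or self.role} covers no pixels")
        return m

    def area_px(self, shape: tuple[int, int] | None = None) -> int:
        if self.rect is not None:
            return self.rect[2] * self.rect[3]
        if shape is None:
            r1 = int(np.ceil(max(v[0] for v in self.vertices))) + 2
            c1 = int(np.ceil(max(v[1] for v in self.vertices))) + 2
            shape = (max(r1, 16), max(c1, 16))
            m = np.zeros(shape, dtype=bool)
            rows = np.array([v[0] for v in self.vertices])
            cols = np.array([v[1] for v in self.vertices])
            rr, cc = _sk_polygon(rows, cols, shape=shape)
            m[rr, cc] = True
            return int(m.sum())
        return int(self.mask(shape).sum())

    def area_um2(self, pixel_size_nm: float, shape: tuple[int, int] | None = None) -> float:
        return self.area_px(shape) * (pixel_size_nm / 1000.0) ** 2

    @staticmethod
    def full_frame(shape: tuple[int, int], role: str = "membrane", name: str = "frame") -> "Roi":
        return Roi(rect=(0, 0, shape[0], shape[1]), role=role, name=name)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the maxima / association analysis.

    Defaults follow the published procedure: Gaussian blur sigma of 1 px
    before thresholding, an absolute intensity threshold in the 1-5 a.u.
    range (default 2), 50 nm cutoff for close cross-channel association,
    15 x 3 px line scans for FWHM fitting with an R^2 >= 0.8 acceptance
    rule, and 25 nm histogram bins (one STED pixel).
    """

    blur_sigma_px: float = 1.0
    maxima_threshold_au: float = 2.0
    close_cutoff_nm: float = 50.0
    linescan_length_px: int = 15
    linescan_width_px: int = 3
    r2_min: float = 0.8
    histogram_bin_nm: float = 25.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "blur_sigma_px",
            "maxima_threshold_au",
            "close_cutoff_nm",
            "linescan_length_px",
            "linescan_width_px",
            "histogram_bin_nm",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 < self.r2_min < 1:
            raise ValueError(f"r2_min must be in (0,1), got {self.r2_min}")
        if self.linescan_length_px % 2 != 1:
            raise ValueError("linescan_length_px must be odd so a scan can be centered")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file; missing keys use defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return AnalysisConfig(**data)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(cfg, k) for k in cfg.__dataclass_fields__}, fh)


def read_micrograph(
    path: str | Path,
    pixel_size_nm: float,
    channel: str = "",
    condition: str = "",
) -> list[Micrograph]:
    """Read a grayscale TIFF into one :class:`Micrograph` per page.

    Integer TIFFs round-trip bit-exactly. RGB input is rejected: channels
    must be supplied as separate grayscale planes so that the registration
    check stays explicit.
    """
    path = Path(path)
    if not (np.isfinite(pixel_size_nm) and pixel_size_nm > 0):
        raise ValueError(f"non-positive pixel size for {path}: {pixel_size_nm}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file named
        raise ValueError(f"cannot read TIFF file {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected grayscale 2D page(s), got shape {pages.shape}")
    if pages.shape[-1] in (3, 4) and pages.shape[-1] < min(pages.shape[:-1]):
        raise ValueError(f"{path}: RGB(A) TIFF not supported; supply grayscale channels")
    out = []
    for i, plane in enumerate(pages):
        label = channel if pages.shape[0] == 1 else f"{channel or 'ch'}:{i}"
        out.append(
            Micrograph(plane, pixel_size_nm=pixel_size_nm, channel=label, condition=condition)
        )
    return out


def write_micrograph(img: Micrograph, path: str | Path) -> None:
    """Write a micrograph as a single-page grayscale TIFF (lossless for integer data)."""
    tifffile.imwrite(Path(path), img.pixels)


def _roi_to_record(roi: Roi) -> dict:
    rec: dict = {"role": roi.role, "name": roi.name}
    if roi.rect is not None:
        rec["shape"] = "rectangle"
        rec["row0"], rec["col0"], rec["height"], rec["width"] = roi.rect
    else:
        rec["shape"] = "polygon"
        rec["vertices"] = [list(v) for v in roi.vertices]
    return rec


def _roi_from_record(rec: dict) -> Roi:
    shape = rec.get("shape", "rectangle")
    if shape == "rectangle":
        return Roi(
            rect=(int(rec["row0"]), int(rec["col0"]), int(rec["height"]), int(rec["width"])),
            role=rec.get("role", "membrane"),
            name=rec.get("name", ""),
        )
    if shape == "polygon":
        return Roi(
            vertices=tuple((float(r), float(c)) for r, c in rec["vertices"]),
            role=rec.get("role", "membrane"),
            name=rec.get("name", ""),
        )
    raise ValueError(f"unknown ROI shape {shape!r}")


def load_rois(path: str | Path, image_shape: tuple[int, int] | None = None) -> list[Roi]:
    """Load ROIs from JSON (list of records) or CSV (rectangles only).

    If ``image_shape`` is given, every ROI is validated against it and
    out-of-bounds regions are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise ValueError(f"{path}: expected a JSON list of ROI records")
        rois = [_roi_from_record(r) for r in records]
    else:
        df = pd.read_csv(path)
        required = {"row0", "col0", "height", "width"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: ROI CSV needs columns {sorted(required)}")
        rois = [
            Roi(
                rect=(int(r.row0), int(r.col0), int(r.height), int(r.width)),
                role=getattr(r, "role", "membrane"),
                name=str(getattr(r, "name", "")),
            )
            for r in df.itertuples()
        ]
    if image_shape is not None:
        for roi in rois:
            roi.validate_inside(image_shape)
    return rois


def save_rois(rois: Iterable[Roi], path: str | Path) -> None:
    """Write ROIs to JSON; the polygon round trip preserves vertices."""
    with open(Path(path), "w") as fh:
        json.dump([_roi_to_record(r) for r in rois], fh, indent=1)
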