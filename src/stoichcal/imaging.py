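"""Circular-ROI CT-number extraction and a synthetic phantom scanner.

The virtual scanner renders a 2-D phantom slice on a pixel grid: each
pixel takes the theoretical CT number of the material at its centre under
ground-truth attenuation parameters, plus independent Gaussian noise at a
typical scanner magnitude (a few HU).  Circular regions of interest are
averaged with a centre-in-circle pixel membership rule and, by default,
an ROI diameter of 0.7 times the insert diameter so the ROI stays clear
of the insert boundary.

The default phantom layout mirrors a compact postal audit phantom: a
150 mm x 150 mm water-equivalent body carrying 20-mm lung-, bone-, and
water-equivalent inserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import AUDIT_PHANTOM_MATERIALS, FORMULA_MATERIALS
from .materials import MaterialComposition
from .model import AttenuationParams, CTMeasurement, theoretical_hu

__all__ = [
    "ImageGrid",
    "ROISpec",
    "VirtualScanner",
    "PhantomInsert",
    "PhantomLayout",
    "default_audit_layout",
    "roi_mean",
    "simulate_image",
    "measure_phantom",
    "DEFAULT_ROI_FRACTION",
]

DEFAULT_ROI_FRACTION = 0.7


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D HU image with isotropic pixel spacing (mm).

    ``origin`` is the physical (x, y) position of the centre of pixel
    (row 0, col 0); x runs along columns, y along rows.
    """

    pixels: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of every pixel centre."""
        ny, nx = self.pixels.shape
        x = self.origin[0] + np.arange(nx) * self.spacing
        y = self.origin[1] + np.arange(ny) * self.spacing
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class ROISpec:
    """A circular region of interest: physical centre (mm) and diameter (mm)."""

    center: tuple[float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")


@dataclass(frozen=True)
class VirtualScanner:
    """Ground-truth attenuation parameters plus per-pixel Gaussian HU noise."""

    truth: AttenuationParams
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class PhantomInsert:
    material: MaterialComposition
    center: tuple[float, float]
    diameter: float


@dataclass(frozen=True)
class PhantomLayout:
    """Rectangular phantom body with circular material inserts."""

    body: MaterialComposition
    size: tuple[float, float]  # (width, height) mm
    inserts: tuple[PhantomInsert, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inserts", tuple(self.inserts))
        w, h = self.size
        for ins in self.inserts:
            x, y = ins.center
            r = ins.diameter / 2
            if not (r <= x <= w - r and r <= y <= h - r):
                raise ValueError(f"insert {ins.material.name} extends beyond the body")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1:]:
                gap = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if gap < (a.diameter + b.diameter) / 2:
                    raise ValueError(
                        f"inserts {a.material.name} and {b.material.name} overlap"
                    )


def default_audit_layout() -> PhantomLayout:
    """150 x 150 mm tough-water body with 20-mm lung, bone, and water inserts."""
    return PhantomLayout(
        body=AUDIT_PHANTOM_MATERIALS["tough_water"],
        size=(150.0, 150.0),
        inserts=(
            PhantomInsert(AUDIT_PHANTOM_MATERIALS["tough_lung"], (45.0, 75.0), 20.0),
            PhantomInsert(AUDIT_PHANTOM_MATERIALS["tough_bone"], (105.0, 75.0), 20.0),
            PhantomInsert(FORMULA_MATERIALS["water"], (75.0, 110.0), 20.0),
        ),
    )


def roi_mean(img: ImageGrid, roi: ROISpec) -> tuple[float, float, int]:
    """Mean and SD of the HU values whose pixel centres fall inside the ROI.

    Returns ``(mean, sd, n_pixels)``.  The ROI must lie fully inside the
    grid and contain at least one pixel centre.
    """
    ny, nx = img.pixels.shape
    r = roi.diameter / 2.0
    cx, cy = roi.center
    x_lo, y_lo = img.origin
    x_hi = x_lo + (nx - 1) * img.spacing
    y_hi = y_lo + (ny - 1) * img.spacing
    if cx - r < x_lo - img.spacing / 2 or cx + r > x_hi + img.spacing / 2 \
            or cy - r < y_lo - img.spacing / 2 or cy + r > y_hi + img.spacing / 2:
        raise ValueError("ROI extends outside the image grid")
    X, Y = img.pixel_centers()
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI contains no pixel centres")
    vals = img.pixels[mask]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(np.mean(vals)), sd, n


def simulate_image(
    layout: PhantomLayout,
    scanner: VirtualScanner,
    spacing: float = 1.0,
) -> ImageGrid:
    """Render a noiseless material map through the ground-truth HU model,
    then add independent Gaussian noise.  Deterministic for a given seed."""
    w, h = layout.size
    nx = int(round(w / spacing))
    ny = int(round(h / spacing))
    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    X, Y = np.meshgrid(x, y)

    pixels = np.full(
        (ny, nx), theoretical_hu(layout.body, scanner.truth), dtype=float
    )
    for ins in layout.inserts:
        hu = theoretical_hu(ins.material, scanner.truth)
        mask = (X - ins.center[0]) ** 2 + (Y - ins.center[1]) ** 2 \
            <= (ins.diameter / 2) ** 2
        pixels[mask] = hu
    if scanner.noise_sd > 0:
        rng = np.random.default_rng(scanner.seed)
        pixels = pixels + rng.normal(0.0, scanner.noise_sd, pixels.shape)
    return ImageGrid(pixels, spacing, origin=(0.5 * spacing, 0.5 * spacing))


def measure_phantom(
    img: ImageGrid,
    layout: PhantomLayout,
    roi_fraction: float = DEFAULT_ROI_FRACTION,
) -> list[CTMeasurement]:
    """One CT measurement per insert, via a centred circular ROI of
    ``roi_fraction`` times the insert diameter."""
    if roi_fraction >= 1.0:
        warnings.warn(
            "roi_fraction >= 1: ROI touches or exceeds the insert boundary",
            stacklevel=2,
        )
    out = []
    for ins in layout.inserts:
        mean, sd, _n = roi_mean(
            img, ROISpec(ins.center, roi_fraction * ins.diameter)
        )
        out.append(CTMeasurement(ins.material, mean, sd))
    return out
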