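"""Pixel-level quantifications: colocalization, puncta, size–frequency.

Implements the image metrics used for cell-level phenotyping: Pearson
correlation of two fluorescence channels over a thresholded region of
interest (colocalization: rho = 1; exclusion: rho = −1), detection of
puncta (aggregates, lysosomes) as connected components above threshold,
per-cell punctum assignment, and size–frequency summaries such as the
fraction of lysosomes with equivalent diameter above 5 and 10 μm.

Thresholds default to Otsu's method computed within the region of
interest; connected components use 8-connectivity (the common Fiji
default) and a minimum area of 4 pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops


@dataclass
class ImageChannel:
    """A single 2D grayscale channel with physical pixel size (μm/pixel)."""

    data: np.ndarray
    pixel_size: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("channel data must be 2D")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class RoiMask:
    """Boolean region-of-interest mask congruent with its channel."""

    mask: np.ndarray
    region_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one true pixel")


@dataclass
class Punctum:
    label: int
    area_px: int
    equivalent_diameter_um: float
    centroid: tuple[float, float]  # (row, col) in pixels


@dataclass
class PunctaSet:
    puncta: list[Punctum] = field(default_factory=list)
    source_region: str = ""

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def diameters_um(self) -> list[float]:
        return [p.equivalent_diameter_um for p in self.puncta]


def _resolve_threshold(
    data: np.ndarray, mask: np.ndarray | None, threshold: float | str
) -> float:
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold scheme {threshold!r}")
        values = data[mask] if mask is not None else data.ravel()
        if np.all(values == values.flat[0]):
            # constant region: Otsu undefined; place threshold at the value so
            # nothing is strictly above it
            return float(values.flat[0])
        return float(threshold_otsu(values))
    return float(threshold)


@dataclass
class ColocalizationResult:
    rho: float
    n_pixels: int
    threshold1: float
    threshold2: float


def pearson_colocalization(
    ch1: ImageChannel,
    ch2: ImageChannel,
    roi: RoiMask,
    thresholds: tuple[float | str, float | str] = ("otsu", "otsu"),
) -> ColocalizationResult:
    """Pearson correlation of paired intensities over a thresholded ROI.

    Qualifying pixels are ROI pixels where at least one channel exceeds its
    threshold (strictly).  Thresholds may be numeric or ``"otsu"`` (computed
    within the ROI per channel).  Raises if fewer than two qualifying pixels
    remain or either channel has zero variance over them.

    The coefficient is computed from centered dot products; values within
    1e-12 of ±1 are snapped to exactly ±1 so that perfectly identical or
    affine-inverted channels report 1.0 and −1.0.
    """
    if ch1.data.shape != ch2.data.shape or ch1.data.shape != roi.mask.shape:
        raise ValueError("channels and mask must be congruent")
    t1 = _resolve_threshold(ch1.data, roi.mask, thresholds[0])
    t2 = _resolve_threshold(ch2.data, roi.mask, thresholds[1])
    qualify = roi.mask & ((ch1.data > t1) | (ch2.data > t2))
    n = int(qualify.sum())
    if n < 2:
        raise ValueError("undefined correlation: fewer than 2 qualifying pixels")
    x = ch1.data[qualify].astype(float)
    y = ch2.data[qualify].astype(float)
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("undefined correlation: zero variance in a channel")
    rho = float(dx @ dy) / math.sqrt(sxx * syy)
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = math.copysign(1.0, rho)
    rho = min(1.0, max(-1.0, rho))
    return ColocalizationResult(rho=rho, n_pixels=n, threshold1=t1, threshold2=t2)


def detect_puncta(
    ch: ImageChannel,
    threshold: float | str = "otsu",
    min_area: int = 4,
    roi: RoiMask | None = None,
) -> PunctaSet:
    """Detect puncta as 8-connected components strictly above threshold.

    Components smaller than ``min_area`` pixels are discarded.  Equivalent
    diameter is that of the circle with the component's physical area:
    ``2 * sqrt(area_um2 / pi)``.  An empty set is a valid result.
    """
    mask = roi.mask if roi is not None else None
    t = _resolve_threshold(ch.data, mask, threshold)
    binary = ch.data > t
    if mask is not None:
        binary &= mask
    labeled = cc_label(binary, connectivity=2)
    puncta = []
    for rp in regionprops(labeled):
        if rp.area < min_area:
            continue
        area_um2 = float(rp.area) * ch.pixel_size**2
        puncta.append(
            Punctum(
                label=int(rp.label),
                area_px=int(rp.area),
                equivalent_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return PunctaSet(puncta=puncta, source_region=roi.region_id if roi else "")


@dataclass
class PerCellPuncta:
    counts: dict[str, int]
    diameters: dict[str, list[float]]
    unassigned: list[Punctum]


def puncta_per_cell(
    ch: ImageChannel,
    cell_masks: list[RoiMask],
    threshold: float | str = "otsu",
    min_area: int = 4,
) -> PerCellPuncta:
    """Assign detected puncta to cells by centroid membership.

    Masks must be pairwise disjoint.  A punctum whose centroid pixel falls
    outside every mask is reported in ``unassigned``.
    """
    if not cell_masks:
        raise ValueError("need at least one cell mask")
    total = np.zeros(ch.data.shape, dtype=int)
    for m in cell_masks:
        if m.mask.shape != ch.data.shape:
            raise ValueError("mask shape must match channel")
        total += m.mask.astype(int)
    if np.any(total > 1):
        raise ValueError("overlapping cell masks")

    puncta = detect_puncta(ch, threshold=threshold, min_area=min_area)
    counts = {m.region_id: 0 for m in cell_masks}
    diameters: dict[str, list[float]] = {m.region_id: [] for m in cell_masks}
    unassigned: list[Punctum] = []
    nrow, ncol = ch.data.shape
    for p in puncta.puncta:
        r = min(max(int(round(p.centroid[0])), 0), nrow - 1)
        c = min(max(int(round(p.centroid[1])), 0), ncol - 1)
        for m in cell_masks:
            if m.mask[r, c]:
                counts[m.region_id] += 1
                diameters[m.region_id].append(p.equivalent_diameter_um)
                break
        else:
            unassigned.append(p)
    return PerCellPuncta(counts=counts, diameters=diameters, unassigned=unassigned)


@dataclass
class SizeFrequency:
    fractions: dict[float, float]  # cutoff μm -> fraction strictly above
    total_count: int
    mean_diameter_um: float


def size_frequency(
    puncta: PunctaSet, cutoffs: list[float] = (5.0, 10.0)
) -> SizeFrequency:
    """Fraction of puncta with equivalent diameter strictly above each cutoff."""
    if len(puncta) == 0:
        raise ValueError("empty puncta set")
    diam = np.asarray(puncta.diameters_um, dtype=float)
    fractions = {
        float(c): float(np.mean(diam > c)) for c in cutoffs
    }
    return SizeFrequency(
        fractions=fractions,
        total_count=int(diam.size),
        mean_diameter_um=float(diam.mean()),
    )
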