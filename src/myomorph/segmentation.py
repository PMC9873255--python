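"""Fiber segmentation and myosin-heavy-chain fiber typing.

Sections are stained so that the laminin channel outlines every fiber;
fibers are the connected components of the sub-threshold (non-boundary)
phase of that channel.  Fiber types are read from the three MHC channels:
a fiber positive in exactly one channel takes that type, a fiber dark in
all three is type 2x, and a multi-positive fiber is assigned to the
channel with the largest min--max-normalized signal and flagged hybrid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ConfigurationError, DegenerateInputError
from .thresholding import foreground_threshold, huang_threshold_image

__all__ = [
    "CHANNEL_ROLES",
    "MHC_CHANNELS",
    "SectionImage",
    "FiberROI",
    "segment_fibers",
    "assign_fiber_types",
]

#: canonical channel roles; extra marker channels (e.g. PDGFRa/Pax7 stains) are allowed
CHANNEL_ROLES = ("laminin", "mhc1", "mhc2a", "mhc2b", "dapi", "hematoxylin", "redstain")

#: MHC channel role -> fiber type it marks
MHC_CHANNELS = {"mhc1": "1", "mhc2a": "2a", "mhc2b": "2b"}


@dataclass
class SectionImage:
    """A multi-channel stained-section raster.

    Parameters
    ----------
    channels : dict of role -> 2-D float array
        All channels must share one shape.
    pixel_size : float
        Physical pixel size in micrometers per pixel.
    tissue_mask : 2-D bool array, optional
        True over the tissue cross-section.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    tissue_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.channels:
            raise ConfigurationError("SectionImage needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ConfigurationError(f"channel shapes differ: {shapes}")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.tissue_mask is not None and self.tissue_mask.shape != self.shape:
            raise ConfigurationError("tissue_mask shape does not match channels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise ConfigurationError(f"channel role {role!r} not present") from None


@dataclass
class FiberROI:
    """One segmented fiber: a pixel region plus derived attributes.

    Coordinates are pixel-center, row-major, 0-based.  ``mask`` is the
    boolean region within the bounding box ``bbox`` = (rmin, cmin, rmax,
    cmax) with exclusive maxima; ``area`` is |pixels| * pixel_size**2 in um^2.
    """

    label: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    area: float
    touches_border: bool
    channel_means: dict[str, float] = field(default_factory=dict)
    fiber_type: str | None = None
    hybrid: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        r0, c0 = self.bbox[0], self.bbox[1]
        return float(rr.mean() + r0), float(cc.mean() + c0)


def _eroded_mean(channel: np.ndarray, roi: FiberROI, erode_px: int = 1) -> float:
    """Mean intensity inside the ROI eroded by ``erode_px`` (guards boundary bleed).

    Falls back to the full ROI if erosion empties it (tiny fibers).
    """
    r0, c0, r1, c1 = roi.bbox
    mask = roi.mask
    if erode_px > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erode_px)
        if eroded.any():
            mask = eroded
    return float(channel[r0:r1, c0:c1][mask].mean())


def segment_fibers(
    image: SectionImage,
    min_area: float = 100.0,
    max_area: float | None = None,
    exclude_border: bool = True,
) -> list[FiberROI]:
    """Segment fiber ROIs from the laminin channel.

    The laminin channel is binarized with the Huang threshold; fibers are
    the 4-connected components of the sub-threshold phase.  Components
    touching the image border are removed when ``exclude_border`` is set,
    and components outside ``[min_area, max_area]`` (um^2) are dropped.

    Returns a list of disjoint :class:`FiberROI`; an empty list (with a
    warning) if no component survives filtering.
    """
    laminin = image.channel("laminin")
    try:
        thr = huang_threshold_image(laminin)
    except DegenerateInputError:
        raise DegenerateInputError("laminin channel is constant; nothing to segment")
    interior = laminin <= thr
    if not interior.any():
        raise DegenerateInputError("laminin channel thresholded to all boundary")

    labels = measure.label(interior, connectivity=1)
    px_area = image.pixel_size ** 2
    h, w = labels.shape
    rois: list[FiberROI] = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if exclude_border and touches:
            continue
        area = region.area * px_area
        if area < min_area or (max_area is not None and area > max_area):
            continue
        roi = FiberROI(
            label=int(region.label),
            bbox=(r0, c0, r1, c1),
            mask=region.image.copy(),
            area=float(area),
            touches_border=bool(touches),
        )
        roi.channel_means = {
            role: _eroded_mean(ch, roi) for role, ch in image.channels.items()
        }
        rois.append(roi)
    if not rois:
        warnings.warn("no fiber ROI survived filtering", stacklevel=2)
    return rois


def assign_fiber_types(
    rois: list[FiberROI],
    image: SectionImage,
    positivity_thresholds: dict[str, float] | None = None,
) -> list[FiberROI]:
    """Assign a fiber type to each ROI from its mean MHC signals (in place).

    Each MHC channel is scored positive when the ROI's mean intensity in
    the 1-px-eroded region exceeds that channel's positivity threshold
    (by default the Huang threshold of the whole-channel histogram; a
    constant channel scores nothing positive).  Exactly one positive
    channel gives that type; none gives 2x; multiple positives resolve to
    the largest min--max-normalized signal with the hybrid flag set.
    """
    for role in MHC_CHANNELS:
        if role not in image.channels:
            raise ConfigurationError(f"fiber typing requires channel {role!r}")

    thresholds: dict[str, float] = {}
    norms: dict[str, tuple[float, float]] = {}
    for role in MHC_CHANNELS:
        ch = image.channels[role]
        lo, hi = float(ch.min()), float(ch.max())
        norms[role] = (lo, hi)
        if positivity_thresholds is not None and role in positivity_thresholds:
            thresholds[role] = positivity_thresholds[role]
        else:
            # bimodality-guarded threshold: a channel with no stained
            # fibers (constant, or pure noise) scores nothing positive
            thr = foreground_threshold(ch)
            thresholds[role] = np.inf if thr is None else thr

    for roi in rois:
        means = {role: roi.channel_means[role] for role in MHC_CHANNELS}
        positive = [r for r in MHC_CHANNELS if means[r] > thresholds[r]]
        roi.hybrid = False
        if not positive:
            roi.fiber_type = "2x"
        elif len(positive) == 1:
            roi.fiber_type = MHC_CHANNELS[positive[0]]
        else:
            def normalized(role: str) -> float:
                lo, hi = norms[role]
                return (means[role] - lo) / (hi - lo) if hi > lo else 0.0

            best = max(positive, key=normalized)
            roi.fiber_type = MHC_CHANNELS[best]
            roi.hybrid = True
    return rois
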