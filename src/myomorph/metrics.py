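"""Section-level quantification: CSA statistics, stain area fractions,
central nuclei, basophilic puncta, and marker-cell counts.

All percentages are percent of fibers; fractions are dimensionless in
[0, 1]; areas are um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .segmentation import FiberROI, SectionImage
from .thresholding import foreground_threshold, huang_threshold_image

__all__ = [
    "CSAStat",
    "SectionMetrics",
    "csa_statistics",
    "area_fraction",
    "count_central_nuclei",
    "count_basophilic_puncta",
    "count_marker_cells",
    "quantify_section",
]


@dataclass
class CSAStat:
    """Per-type CSA summary: arithmetic mean and a fixed-width histogram
    with bins starting at 0."""

    fiber_type: str
    n: int
    mean: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class SectionMetrics:
    """Outcome set for one section."""

    fiber_number: int
    csa: dict[str, CSAStat]
    type_fractions: dict[str, float]
    central_nuclei_pct: float | None = None
    puncta_pct: float | None = None
    fibrosis_fraction: float | None = None
    fat_fraction: float | None = None
    faps_per_fiber: float | None = None
    scs_per_fiber: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fiber_number": self.fiber_number,
            "csa_mean_um2": {t: s.mean for t, s in self.csa.items()},
            "csa_n": {t: s.n for t, s in self.csa.items()},
            "type_fractions": self.type_fractions,
            "central_nuclei_pct": self.central_nuclei_pct,
            "puncta_pct": self.puncta_pct,
            "fibrosis_fraction": self.fibrosis_fraction,
            "fat_fraction": self.fat_fraction,
            "faps_per_fiber": self.faps_per_fiber,
            "scs_per_fiber": self.scs_per_fiber,
            **self.extras,
        }


def csa_statistics(rois: list[FiberROI], bin_width: float = 200.0) -> dict[str, CSAStat]:
    """Per-type mean CSA and histogram over typed ROIs.

    Types with no fibers are absent from the result (missing, not zero).
    """
    if not rois:
        raise DegenerateInputError("no ROIs to summarize")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    by_type: dict[str, list[float]] = {}
    for roi in rois:
        if roi.fiber_type is None:
            continue
        by_type.setdefault(roi.fiber_type, []).append(roi.area)
    if not by_type:
        raise DegenerateInputError("no typed ROIs; run assign_fiber_types first")
    out: dict[str, CSAStat] = {}
    for ftype, areas in by_type.items():
        arr = np.asarray(areas, dtype=float)
        n_bins = max(1, int(np.ceil(arr.max() / bin_width)))
        edges = np.arange(n_bins + 1, dtype=float) * bin_width
        counts, _ = np.histogram(arr, bins=edges)
        out[ftype] = CSAStat(
            fiber_type=ftype,
            n=arr.size,
            mean=float(arr.mean()),
            bin_edges=edges,
            counts=counts,
        )
    return out


def area_fraction(
    image: SectionImage, channel_role: str, tissue_mask: np.ndarray | None = None
) -> float:
    """Fraction of tissue pixels above the channel's Huang threshold.

    An all-background (constant) channel yields 0.0.
    """
    channel = image.channel(channel_role)
    if tissue_mask is None:
        tissue_mask = (
            image.tissue_mask
            if image.tissue_mask is not None
            else np.ones(channel.shape, dtype=bool)
        )
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise DegenerateInputError("empty tissue mask")
    try:
        thr = huang_threshold_image(channel)
    except DegenerateInputError:
        return 0.0
    positive = channel > thr
    return float((positive & tissue_mask).sum() / n_tissue)


def _threshold_mask(channel: np.ndarray) -> np.ndarray:
    """Foreground mask of a channel; no credible foreground -> empty mask."""
    thr = foreground_threshold(channel)
    if thr is None:
        return np.zeros(channel.shape, dtype=bool)
    return channel > thr


def _blob_centroids_and_slices(mask: np.ndarray):
    labels, n = ndimage.label(mask)  # 8-connectivity default for blobs
    if n == 0:
        return labels, []
    centroids = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
    return labels, list(enumerate(centroids, start=1))


def _roi_label_maps(
    rois: list[FiberROI], shape: tuple[int, int], margin: int
) -> tuple[np.ndarray, np.ndarray]:
    """(full, eroded) int maps: pixel -> 1-based ROI index, 0 elsewhere."""
    full = np.zeros(shape, dtype=np.int32)
    eroded = np.zeros(shape, dtype=np.int32)
    for i, roi in enumerate(rois, start=1):
        r0, c0, r1, c1 = roi.bbox
        full[r0:r1, c0:c1][roi.mask] = i
        if margin > 0:
            core = ndimage.binary_erosion(roi.mask, iterations=margin)
        else:
            core = roi.mask
        eroded[r0:r1, c0:c1][core] = i
    return full, eroded


def _centroid_index(centroid: tuple[float, float], label_map: np.ndarray) -> int:
    r = int(round(centroid[0]))
    c = int(round(centroid[1]))
    r = min(max(r, 0), label_map.shape[0] - 1)
    c = min(max(c, 0), label_map.shape[1] - 1)
    return int(label_map[r, c])


def _dapi_overlap_positive(
    labels: np.ndarray, blob_id: int, dapi_mask: np.ndarray
) -> bool:
    blob = labels == blob_id
    return dapi_mask[blob].mean() >= 0.5


def count_central_nuclei(
    rois: list[FiberROI], image: SectionImage, margin: int = 2
) -> float:
    """Percent of fibers containing >= 1 central nucleus.

    A nucleus is a blob positive in both hematoxylin and DAPI; it is
    central when its centroid lies inside a fiber ROI eroded by
    ``margin`` pixels (nuclei straddling the laminin boundary fail the
    erosion test).
    """
    if not rois:
        raise DegenerateInputError("no fiber ROIs")
    hema = _threshold_mask(image.channel("hematoxylin"))
    dapi = _threshold_mask(image.channel("dapi"))
    labels, blobs = _blob_centroids_and_slices(hema)
    _, eroded_map = _roi_label_maps(rois, image.shape, margin)
    flagged: set[int] = set()
    for blob_id, centroid in blobs:
        if not _dapi_overlap_positive(labels, blob_id, dapi):
            continue
        idx = _centroid_index(centroid, eroded_map)
        if idx > 0:
            flagged.add(idx)
    return 100.0 * len(flagged) / len(rois)


def count_basophilic_puncta(
    rois: list[FiberROI], image: SectionImage, margin: int = 2
) -> float:
    """Percent of fibers containing >= 1 basophilic punctum.

    A punctum is a blob positive in hematoxylin but negative in DAPI
    (DAPI-positive blobs are nuclei and are excluded), centered inside a
    fiber ROI eroded by ``margin``.
    """
    if not rois:
        raise DegenerateInputError("no fiber ROIs")
    hema = _threshold_mask(image.channel("hematoxylin"))
    dapi = _threshold_mask(image.channel("dapi"))
    labels, blobs = _blob_centroids_and_slices(hema)
    _, eroded_map = _roi_label_maps(rois, image.shape, margin)
    flagged: set[int] = set()
    for blob_id, centroid in blobs:
        if _dapi_overlap_positive(labels, blob_id, dapi):
            continue
        idx = _centroid_index(centroid, eroded_map)
        if idx > 0:
            flagged.add(idx)
    return 100.0 * len(flagged) / len(rois)


def count_marker_cells(
    rois: list[FiberROI],
    image: SectionImage,
    marker_channel: str,
    compartment: str,
    margin: int = 2,
) -> float:
    """Marker-positive cells per fiber in one compartment.

    ``interstitial`` counts blobs whose centroid lies outside every fiber
    ROI (between laminin boundaries; FAP-like).  ``sublaminar`` counts
    blobs whose centroid lies inside a fiber ROI within ``margin`` pixels
    of its boundary (satellite-cell-like).  Blobs deep inside a fiber
    fall in neither compartment.
    """
    if compartment not in ("interstitial", "sublaminar"):
        raise ConfigurationError(f"unknown compartment {compartment!r}")
    if not rois:
        raise DegenerateInputError("no fiber ROIs")
    marker = _threshold_mask(image.channel(marker_channel))
    _, blobs = _blob_centroids_and_slices(marker)
    full_map, eroded_map = _roi_label_maps(rois, image.shape, margin)
    count = 0
    for _, centroid in blobs:
        in_full = _centroid_index(centroid, full_map)
        in_core = _centroid_index(centroid, eroded_map)
        if compartment == "interstitial" and in_full == 0:
            count += 1
        elif compartment == "sublaminar" and in_full > 0 and in_core == 0:
            count += 1
    return count / len(rois)


def quantify_section(
    rois: list[FiberROI],
    image: SectionImage,
    bin_width: float = 200.0,
    margin: int = 2,
    fap_channel: str | None = None,
    sc_channel: str | None = None,
) -> SectionMetrics:
    """Assemble the full :class:`SectionMetrics` for one segmented section."""
    if not rois:
        raise DegenerateInputError("no fiber ROIs")
    csa = csa_statistics(rois, bin_width=bin_width)
    typed = [r for r in rois if r.fiber_type is not None]
    fractions = {
        t: sum(1 for r in typed if r.fiber_type == t) / len(typed) for t in csa
    }
    metrics = SectionMetrics(
        fiber_number=len(rois), csa=csa, type_fractions=fractions
    )
    if "hematoxylin" in image.channels and "dapi" in image.channels:
        metrics.central_nuclei_pct = count_central_nuclei(rois, image, margin)
        metrics.puncta_pct = count_basophilic_puncta(rois, image, margin)
    if "redstain" in image.channels:
        metrics.fat_fraction = area_fraction(image, "redstain")
    if fap_channel and fap_channel in image.channels:
        metrics.faps_per_fiber = count_marker_cells(
            rois, image, fap_channel, "interstitial", margin
        )
    if sc_channel and sc_channel in image.channels:
        metrics.scs_per_fiber = count_marker_cells(
            rois, image, sc_channel, "sublaminar", margin
        )
    return metrics
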