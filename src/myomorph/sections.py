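"""Synthetic stained-section generator with pixel-exact ground truth.

The tissue cross-section is a disk.  Fibers are built by a bounded
random tessellation: Poisson-disk-sampled centroids, nearest-centroid
(Voronoi) cells clipped to the disk, shrunk by a laminin ribbon so that
fiber interiors are pairwise disjoint and the ribbon is exactly the
tissue complement of their union.  Each fiber gets one MHC type; type 2x
fibers are dark in all three MHC channels.  DAPI/hematoxylin nuclei sit
on boundaries, plus central nuclei and hematoxylin-only basophilic
puncta at configurable per-fiber rates.  A red-stain channel is painted
to a requested area fraction of the tissue, and marker channels carry
interstitial (FAP-like) and sublaminar (satellite-cell-like) cells.
Gaussian blur and noise are applied last; the ground truth records the
pre-noise construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import measure

from .errors import ConfigurationError, GenerationError
from .segmentation import SectionImage

__all__ = ["SectionSpec", "GroundTruth", "generate_section"]

FIBER_TYPES = ("1", "2a", "2x", "2b")

_DEFAULT_TYPE_FRACTIONS = {"1": 0.02, "2a": 0.28, "2x": 0.30, "2b": 0.40}
# relative size targets (um^2); drive rank-based type/size matching only
_DEFAULT_CSA_MEAN = {"1": 900.0, "2a": 1100.0, "2x": 1800.0, "2b": 2600.0}
_DEFAULT_CSA_SD = {"1": 150.0, "2a": 200.0, "2x": 300.0, "2b": 400.0}


@dataclass
class SectionSpec:
    """Parameters of one synthetic section.

    ``noise_sd`` and ``blur_sd`` are in intensity units / pixels; the
    painted dynamic range is ``bg`` to ``fg``.  Rates are per fiber in
    [0, 1]; ``fat_fraction`` and ``fibrosis_fraction`` are target
    red-positive fractions of the tissue area (their sum is painted into
    the single red-stain channel).
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    n_fibers: int = 120
    ribbon_px: int = 3
    type_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_FRACTIONS)
    )
    csa_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CSA_MEAN))
    csa_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CSA_SD))
    central_nuclei_rate: float = 0.0
    puncta_rate: float = 0.0
    fat_fraction: float = 0.0
    fibrosis_fraction: float = 0.0
    interstitial_cell_rate: float = 0.0
    sublaminar_cell_rate: float = 0.0
    noise_sd: float = 0.0
    blur_sd: float = 0.0
    margin: int = 2
    bg: float = 10.0
    fg: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fibers < 1:
            raise ConfigurationError("n_fibers must be >= 1")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be positive")
        for name in (
            "central_nuclei_rate",
            "puncta_rate",
            "interstitial_cell_rate",
            "sublaminar_cell_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.fat_fraction < 0 or self.fibrosis_fraction < 0:
            raise ConfigurationError("stain fractions must be nonnegative")
        if self.fat_fraction + self.fibrosis_fraction > 1.0:
            raise ConfigurationError("stain fractions must sum to <= 1")
        total = sum(self.type_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(f"type fractions sum to {total}, expected 1")
        if self.noise_sd < 0 or self.blur_sd < 0:
            raise ConfigurationError("noise_sd and blur_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Pre-noise construction record for one synthetic section."""

    label_image: np.ndarray  # 0 = ribbon/background, 1..n = fiber interiors
    tissue_mask: np.ndarray
    ribbon_mask: np.ndarray
    areas_um2: np.ndarray  # per fiber, index i-1 for label i
    types: list[str]
    central_nucleus: np.ndarray  # bool per fiber
    puncta: np.ndarray  # bool per fiber
    polygons: list[Polygon]
    nucleus_centroids: list[tuple[float, float, str]]  # (row, col, kind)
    cell_centroids: list[tuple[float, float, str]]  # (row, col, compartment)
    red_mask: np.ndarray
    pixel_size: float

    @property
    def n_fibers(self) -> int:
        return len(self.types)

    def fiber_mask(self, i: int) -> np.ndarray:
        """Boolean interior mask of 1-based fiber ``i``."""
        return self.label_image == i


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = rr * rr + cc * cc <= radius * radius
    return rr[keep], cc[keep]


def _paint_disk(channel: np.ndarray, r: int, c: int, radius: int, value: float):
    dr, dc = _disk_offsets(radius)
    rr = np.clip(r + dr, 0, channel.shape[0] - 1)
    cc = np.clip(c + dc, 0, channel.shape[1] - 1)
    channel[rr, cc] = value


def _poisson_disk(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    n: int,
    min_dist: float,
) -> np.ndarray:
    """Dart-throwing Poisson-disk sample of ``n`` points inside a disk."""
    points: list[np.ndarray] = []
    max_tries = 600 * n
    tries = 0
    while len(points) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"infeasible packing: placed {len(points)}/{n} fiber centroids"
            )
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * np.sqrt(rng.uniform())
        cand = np.array(
            [center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang)]
        )
        if points:
            d2 = np.sum((np.asarray(points) - cand) ** 2, axis=1)
            if d2.min() < min_dist ** 2:
                continue
        points.append(cand)
    return np.asarray(points)


def _tessellate(spec: SectionSpec, rng: np.random.Generator):
    """One tessellation attempt; returns (label_image, tissue, ribbon) or None."""
    h, w = spec.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tissue_radius = 0.46 * min(h, w)
    rr, cc = np.mgrid[0:h, 0:w]
    tissue = (rr - cy) ** 2 + (cc - cx) ** 2 <= tissue_radius ** 2
    n_tissue = int(tissue.sum())

    cell_area = n_tissue / spec.n_fibers
    min_cell_budget = float((2 * spec.ribbon_px + 6) ** 2)
    if cell_area < min_cell_budget:
        raise GenerationError(
            f"infeasible packing: {spec.n_fibers} fibers leave "
            f"{cell_area:.0f} px per cell (< {min_cell_budget:.0f})"
        )
    min_dist = min(0.8 * np.sqrt(cell_area), 1.1 * tissue_radius)
    centroids = _poisson_disk(
        rng, (cy, cx), max(tissue_radius - 2.0, 1.0), spec.n_fibers, min_dist
    )

    tissue_pts = np.column_stack(np.nonzero(tissue))
    _, nearest = cKDTree(centroids).query(tissue_pts)
    labels = np.zeros((h, w), dtype=np.int32)
    labels[tissue] = nearest + 1

    # boundary seed: pixels whose 4-neighborhood crosses a label change
    edge = np.zeros((h, w), dtype=bool)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.roll(labels, shift, axis=axis)
        edge |= labels != shifted
    edge &= tissue
    dil = (spec.ribbon_px - 1) // 2
    ribbon = ndimage.binary_dilation(edge, iterations=dil) & tissue if dil else edge

    interiors = np.where(ribbon, 0, labels)
    # prune stray pixels so each fiber is one 4-connected region
    floor_px = max(9.0, 110.0 / spec.pixel_size ** 2)
    for i in range(1, spec.n_fibers + 1):
        mask = interiors == i
        lab, ncomp = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if ncomp == 0:
            return None
        if ncomp > 1:
            sizes = ndimage.sum_labels(mask, lab, index=range(1, ncomp + 1))
            keep = int(np.argmax(sizes)) + 1
            stray = mask & (lab != keep)
            if stray.sum() > 4:
                return None
            interiors[stray] = 0
        if (interiors == i).sum() < floor_px:
            return None
    ribbon = tissue & (interiors == 0)
    return interiors, tissue, ribbon


def _deep_pixels(mask: np.ndarray, depth: int) -> np.ndarray:
    """Coordinates at least ``depth`` erosions inside ``mask`` (fallback: deepest pixel)."""
    core = ndimage.binary_erosion(mask, iterations=depth) if depth > 0 else mask
    if not core.any():
        dt = ndimage.distance_transform_edt(mask)
        idx = np.unravel_index(int(np.argmax(dt)), mask.shape)
        return np.array([idx])
    return np.column_stack(np.nonzero(core))


def _pick_separated(
    rng: np.random.Generator,
    candidates: np.ndarray,
    placed: list[tuple[float, float]],
    min_sep: float,
    tries: int = 40,
) -> tuple[int, int] | None:
    for _ in range(tries):
        r, c = candidates[rng.integers(len(candidates))]
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep ** 2 for pr, pc in placed):
            return int(r), int(c)
    return None


def generate_section(spec: SectionSpec) -> tuple[SectionImage, GroundTruth]:
    """Generate one synthetic section and its ground truth.

    Raises
    ------
    GenerationError
        If the requested fiber count cannot be packed into the image.
    """
    rng = np.random.default_rng(spec.seed)
    result = None
    for _ in range(5):
        result = _tessellate(spec, rng)
        if result is not None:
            break
    if result is None:
        raise GenerationError("could not realize a tessellation with all fibers intact")
    interiors, tissue, ribbon = result
    h, w = spec.shape
    n = spec.n_fibers
    px2 = spec.pixel_size ** 2

    masks = [interiors == i for i in range(1, n + 1)]
    areas = np.array([m.sum() * px2 for m in masks])

    # types: multinomial draw, then rank-match sampled target sizes to cell sizes
    type_names = list(spec.type_fractions)
    probs = np.array([spec.type_fractions[t] for t in type_names])
    drawn = rng.choice(len(type_names), size=n, p=probs)
    targets = np.array(
        [
            max(rng.normal(spec.csa_mean[type_names[k]], spec.csa_sd[type_names[k]]), 1.0)
            for k in drawn
        ]
    )
    order_by_area = np.argsort(areas, kind="stable")
    order_by_target = np.argsort(targets, kind="stable")
    types: list[str] = [""] * n
    for fiber_idx, draw_idx in zip(order_by_area, order_by_target):
        types[fiber_idx] = type_names[drawn[draw_idx]]

    channels = {
        role: np.full((h, w), spec.bg, dtype=np.float64)
        for role in (
            "laminin",
            "mhc1",
            "mhc2a",
            "mhc2b",
            "dapi",
            "hematoxylin",
            "redstain",
            "fap_marker",
            "sc_marker",
        )
    }
    channels["laminin"][ribbon] = spec.fg
    type_to_channel = {"1": "mhc1", "2a": "mhc2a", "2b": "mhc2b"}
    for mask, ftype in zip(masks, types):
        if ftype in type_to_channel:  # type 2x stays dark in all three
            channels[type_to_channel[ftype]][mask] = spec.fg

    nucleus_centroids: list[tuple[float, float, str]] = []
    cell_centroids: list[tuple[float, float, str]] = []
    placed: list[tuple[float, float]] = []
    central_flags = np.zeros(n, dtype=bool)
    puncta_flags = np.zeros(n, dtype=bool)

    for i, mask in enumerate(masks):
        # one boundary (sublaminar-ring) nucleus per fiber
        halo = ndimage.binary_dilation(mask, iterations=2) & ribbon
        if halo.any():
            pick = _pick_separated(rng, np.column_stack(np.nonzero(halo)), placed, 7.0)
            if pick is not None:
                _paint_disk(channels["dapi"], *pick, 2, spec.fg)
                _paint_disk(channels["hematoxylin"], *pick, 2, spec.fg)
                placed.append(pick)
                nucleus_centroids.append((*map(float, pick), "boundary"))
        deep = _deep_pixels(mask, spec.margin + 3)
        if rng.random() < spec.central_nuclei_rate:
            pick = _pick_separated(rng, deep, placed, 7.0)
            if pick is not None:
                _paint_disk(channels["dapi"], *pick, 2, spec.fg)
                _paint_disk(channels["hematoxylin"], *pick, 2, spec.fg)
                placed.append(pick)
                central_flags[i] = True
                nucleus_centroids.append((*map(float, pick), "central"))
        if rng.random() < spec.puncta_rate:
            pick = _pick_separated(rng, deep, placed, 7.0)
            if pick is not None:
                _paint_disk(channels["hematoxylin"], *pick, 2, spec.fg)
                placed.append(pick)
                puncta_flags[i] = True
                nucleus_centroids.append((*map(float, pick), "punctum"))
        if rng.random() < spec.interstitial_cell_rate and halo.any():
            pick = _pick_separated(rng, np.column_stack(np.nonzero(halo)), placed, 6.0)
            if pick is not None:
                _paint_disk(channels["fap_marker"], *pick, 1, spec.fg)
                placed.append(pick)
                cell_centroids.append((*map(float, pick), "interstitial"))
        if rng.random() < spec.sublaminar_cell_rate:
            rim = mask & ~ndimage.binary_erosion(mask, iterations=spec.margin)
            if rim.any():
                pick = _pick_separated(rng, np.column_stack(np.nonzero(rim)), placed, 6.0)
                if pick is not None:
                    _paint_disk(channels["sc_marker"], *pick, 1, spec.fg)
                    placed.append(pick)
                    cell_centroids.append((*map(float, pick), "sublaminar"))

    # red stain painted to the requested fraction of tissue, exact to the pixel
    red_target = spec.fat_fraction + spec.fibrosis_fraction
    red_mask = np.zeros((h, w), dtype=bool)
    if red_target > 0:
        k = int(round(red_target * tissue.sum()))
        tissue_coords = np.column_stack(np.nonzero(tissue))
        while (red_mask & tissue).sum() < k:
            r, c = tissue_coords[rng.integers(len(tissue_coords))]
            _paint_disk(red_mask.view(np.uint8).reshape(h, w), r, c, 3, 1)
        excess = int((red_mask & tissue).sum()) - k
        if excess > 0:
            on = np.column_stack(np.nonzero(red_mask & tissue))
            red_mask[tuple(on[-excess:].T)] = False
        channels["redstain"][red_mask & tissue] = spec.fg

    polygons = []
    for mask in masks:
        padded = np.pad(mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        longest = max(contours, key=len)
        poly = Polygon(np.column_stack([longest[:, 1] - 1, longest[:, 0] - 1]))
        polygons.append(poly if poly.is_valid else poly.buffer(0))

    truth = GroundTruth(
        label_image=interiors,
        tissue_mask=tissue,
        ribbon_mask=ribbon,
        areas_um2=areas,
        types=types,
        central_nucleus=central_flags,
        puncta=puncta_flags,
        polygons=polygons,
        nucleus_centroids=nucleus_centroids,
        cell_centroids=cell_centroids,
        red_mask=red_mask & tissue,
        pixel_size=spec.pixel_size,
    )

    for role, ch in channels.items():
        if spec.blur_sd > 0:
            ch = ndimage.gaussian_filter(ch, spec.blur_sd)
        if spec.noise_sd > 0:
            ch = ch + rng.normal(0.0, spec.noise_sd, size=ch.shape)
        channels[role] = ch.astype(np.float32)

    image = SectionImage(
        channels=channels, pixel_size=spec.pixel_size, tissue_mask=tissue
    )
    return image, truth
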