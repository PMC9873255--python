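"""Segmentation, fiber typing, CSA statistics, area fractions, and
pathology/cell counting against generator ground truth and constructed
rule-by-construction cases."""

import numpy as np
import pytest

import myomorph as mm
from myomorph.segmentation import FiberROI


# ---------------------------------------------------------------- helpers
def _toy_image(extra_channels=None):
    """A 64x64 image with two square fibers outlined by laminin."""
    shape = (64, 64)
    channels = {
        role: np.full(shape, 10.0)
        for role in ("laminin", "mhc1", "mhc2a", "mhc2b", "dapi", "hematoxylin")
    }
    lam = channels["laminin"]
    lam[:, :] = 200.0
    fibers = [(slice(8, 28), slice(8, 28)), (slice(36, 56), slice(36, 56))]
    for sl in fibers:
        lam[sl] = 10.0
    if extra_channels:
        for role, patches in extra_channels.items():
            ch = channels.setdefault(role, np.full(shape, 10.0))
            for sl in patches:
                ch[sl] = 200.0
    return mm.SectionImage(channels=channels, pixel_size=1.0), fibers


def _square_roi(label, r0, c0, size, area=None):
    mask = np.ones((size, size), dtype=bool)
    return FiberROI(
        label=label,
        bbox=(r0, c0, r0 + size, c0 + size),
        mask=mask,
        area=float(area if area is not None else size * size),
        touches_border=False,
    )


# ---------------------------------------------------------------- segmentation
def test_segmentation_recovers_ground_truth(segmented_pathology_section, roi_matcher):
    image, truth, rois = segmented_pathology_section
    assert len(rois) == truth.n_fibers
    matched = set()
    for roi in rois:
        idx = roi_matcher(roi, truth)
        assert idx is not None
        matched.add(idx)
        assert abs(roi.area - truth.areas_um2[idx]) / truth.areas_um2[idx] <= 0.05
    assert len(matched) == truth.n_fibers


def test_blank_laminin_raises():
    channels = {"laminin": np.full((32, 32), 7.0)}
    image = mm.SectionImage(channels=channels, pixel_size=1.0)
    with pytest.raises(mm.DegenerateInputError):
        mm.segment_fibers(image)


def test_all_components_filtered_warns():
    image, _ = _toy_image()
    with pytest.warns(UserWarning):
        rois = mm.segment_fibers(image, min_area=1e6)
    assert rois == []


def test_border_and_area_filters():
    image, fibers = _toy_image()
    # carve an extra dark region touching the image border
    image.channels["laminin"][0:10, 40:60] = 10.0
    rois_all = mm.segment_fibers(image, min_area=10.0, exclude_border=False)
    rois = mm.segment_fibers(image, min_area=10.0)
    assert len(rois) == len(fibers)
    assert len(rois_all) == len(fibers) + 1
    assert sum(r.touches_border for r in rois_all) == 1
    with pytest.warns(UserWarning):
        small = mm.segment_fibers(image, min_area=10.0, max_area=199.0)
    assert small == []


# ---------------------------------------------------------------- typing
def test_typing_matches_ground_truth(segmented_pathology_section, roi_matcher):
    image, truth, rois = segmented_pathology_section
    for roi in rois:
        assert roi.fiber_type == truth.types[roi_matcher(roi, truth)]
        assert not roi.hybrid


def test_all_dark_mhc_is_type_2x_and_hybrid_resolution():
    image, fibers = _toy_image()
    # fiber 1 positive in both 2a and 2b with larger normalized 2b signal
    # -> type 2b, hybrid; fiber 2 dark in all three MHC channels -> 2x
    image.channels["mhc2a"][8:28, 8:28] = 200.0
    image.channels["mhc2a"][40, 40] = 255.0  # caps the 2a min-max range below 1
    image.channels["mhc2b"][8:28, 8:28] = 250.0
    rois = mm.segment_fibers(image, min_area=10.0)
    mm.assign_fiber_types(rois, image)
    by_pos = {roi.bbox[0]: roi for roi in rois}
    hybrid_roi = by_pos[8]
    dark_roi = by_pos[36]
    assert dark_roi.fiber_type == "2x" and not dark_roi.hybrid
    assert hybrid_roi.fiber_type == "2b" and hybrid_roi.hybrid


def test_missing_channel_is_configuration_error():
    image, _ = _toy_image()
    del image.channels["mhc1"]
    rois = mm.segment_fibers(image, min_area=10.0)
    with pytest.raises(mm.ConfigurationError):
        mm.assign_fiber_types(rois, image)


# ---------------------------------------------------------------- CSA stats
def test_csa_statistics_examples():
    rois = [
        _square_roi(1, 0, 0, 10, area=1000.0),
        _square_roi(2, 20, 20, 10, area=3000.0),
    ]
    for r in rois:
        r.fiber_type = "2b"
    stats = mm.csa_statistics(rois, bin_width=200.0)
    assert stats["2b"].mean == pytest.approx(2000.0)
    assert stats["2b"].n == 2
    assert "2a" not in stats  # absent type is missing, not zero

    single = mm.csa_statistics(rois[:1], bin_width=200.0)
    assert single["2b"].counts.sum() == 1
    assert (single["2b"].counts > 0).sum() == 1
    assert single["2b"].bin_edges[0] == 0.0


def test_csa_statistics_match_generator(segmented_pathology_section, roi_matcher):
    image, truth, rois = segmented_pathology_section
    stats = mm.csa_statistics(rois)
    for ftype, stat in stats.items():
        truth_mean = np.mean(
            [a for a, t in zip(truth.areas_um2, truth.types) if t == ftype]
        )
        assert stat.mean == pytest.approx(truth_mean, rel=0.05)


# ---------------------------------------------------------------- area fraction
def test_area_fraction_examples():
    shape = (64, 64)
    tissue = np.zeros(shape, dtype=bool)
    tissue[8:56, 8:56] = True
    blank = mm.SectionImage(
        channels={"redstain": np.full(shape, 10.0)}, pixel_size=1.0, tissue_mask=tissue
    )
    assert mm.area_fraction(blank, "redstain") == 0.0
    full = mm.SectionImage(
        channels={"redstain": np.where(tissue, 200.0, 10.0)},
        pixel_size=1.0,
        tissue_mask=tissue,
    )
    assert mm.area_fraction(full, "redstain") == 1.0
    with pytest.raises(mm.DegenerateInputError):
        mm.area_fraction(full, "redstain", tissue_mask=np.zeros(shape, dtype=bool))


def test_area_fraction_recovers_painted_fat(pathology_section):
    image, truth = pathology_section
    target = truth.red_mask.sum() / truth.tissue_mask.sum()
    measured = mm.area_fraction(image, "redstain")
    assert measured == pytest.approx(target, abs=1e-6)


def test_area_fraction_monotone_in_painted_target():
    fractions = [0.02, 0.08, 0.20]
    measured = []
    for f in fractions:
        spec = mm.SectionSpec(shape=(192, 192), n_fibers=15, fat_fraction=f, seed=31)
        image, _ = mm.generate_section(spec)
        measured.append(mm.area_fraction(image, "redstain"))
    assert measured == sorted(measured)


# ---------------------------------------------------------------- counting
def test_central_nuclei_and_puncta_exact(segmented_pathology_section):
    image, truth, rois = segmented_pathology_section
    expected_central = 100.0 * truth.central_nucleus.mean()
    expected_puncta = 100.0 * truth.puncta.mean()
    assert mm.count_central_nuclei(rois, image) == pytest.approx(expected_central)
    assert mm.count_basophilic_puncta(rois, image) == pytest.approx(expected_puncta)


def test_zero_rate_sections_count_zero():
    spec = mm.SectionSpec(shape=(192, 192), n_fibers=20, seed=12)
    image, _ = mm.generate_section(spec)
    rois = mm.segment_fibers(image)
    assert mm.count_central_nuclei(rois, image) == 0.0
    assert mm.count_basophilic_puncta(rois, image) == 0.0
    assert mm.count_marker_cells(rois, image, "fap_marker", "interstitial") == 0.0


def test_boundary_straddling_nucleus_not_central():
    image, fibers = _toy_image()
    # nucleus centered on the laminin boundary at the fiber corner
    for ch in ("dapi", "hematoxylin"):
        image.channels[ch][26:33, 26:33] = 200.0
    rois = mm.segment_fibers(image, min_area=10.0)
    assert mm.count_central_nuclei(rois, image) == 0.0


def test_dapi_positive_blob_is_not_a_punctum():
    image, _ = _toy_image()
    image.channels["hematoxylin"][14:19, 14:19] = 200.0
    image.channels["dapi"][14:19, 14:19] = 200.0
    rois = mm.segment_fibers(image, min_area=10.0)
    assert mm.count_basophilic_puncta(rois, image) == 0.0
    assert mm.count_central_nuclei(rois, image) == pytest.approx(50.0)


def test_marker_cells_exact_in_both_compartments(segmented_pathology_section):
    image, truth, rois = segmented_pathology_section
    n = truth.n_fibers
    exp_inter = sum(1 for *_, k in truth.cell_centroids if k == "interstitial") / n
    exp_sub = sum(1 for *_, k in truth.cell_centroids if k == "sublaminar") / n
    assert mm.count_marker_cells(rois, image, "fap_marker", "interstitial") == pytest.approx(exp_inter)
    assert mm.count_marker_cells(rois, image, "sc_marker", "sublaminar") == pytest.approx(exp_sub)


def test_deep_interior_blob_in_neither_compartment():
    image, _ = _toy_image(extra_channels={"marker": [(slice(16, 20), slice(16, 20))]})
    rois = mm.segment_fibers(image, min_area=10.0)
    assert mm.count_marker_cells(rois, image, "marker", "interstitial") == 0.0
    assert mm.count_marker_cells(rois, image, "marker", "sublaminar") == 0.0


def test_quantify_section_bundles_all_metrics(segmented_pathology_section):
    image, truth, rois = segmented_pathology_section
    metrics = mm.quantify_section(
        rois, image, fap_channel="fap_marker", sc_channel="sc_marker"
    )
    assert metrics.fiber_number == truth.n_fibers
    assert sum(metrics.type_fractions.values()) == pytest.approx(1.0)
    assert 0.0 <= metrics.fat_fraction <= 1.0
    d = metrics.to_dict()
    assert d["central_nuclei_pct"] == pytest.approx(100 * truth.central_nucleus.mean())
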