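import numpy as np
import pytest

import myomorph as mm


@pytest.fixture(scope="session")
def default_effects():
    return mm.EffectModel.default()


@pytest.fixture(scope="session")
def noise_free_effects():
    return mm.EffectModel.default(noise_cv=0.0)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_effects):
    design = mm.CohortDesign(seed=11, n_per_group=3)
    return mm.generate_cohort(design, noise_free_effects)


@pytest.fixture(scope="session")
def pathology_section():
    """One noise-free section exercising every ground-truth feature."""
    spec = mm.SectionSpec(
        shape=(256, 256),
        n_fibers=40,
        central_nuclei_rate=0.25,
        puncta_rate=0.15,
        fat_fraction=0.10,
        interstitial_cell_rate=0.3,
        sublaminar_cell_rate=0.3,
        seed=5,
    )
    return mm.generate_section(spec)


@pytest.fixture(scope="session")
def segmented_pathology_section(pathology_section):
    image, truth = pathology_section
    rois = mm.segment_fibers(image)
    mm.assign_fiber_types(rois, image)
    return image, truth, rois


def match_roi_to_truth(roi, truth):
    """Ground-truth fiber index (0-based) under a segmented ROI's centroid."""
    r, c = roi.centroid()
    label = truth.label_image[int(round(r)), int(round(c))]
    return int(label) - 1 if label > 0 else None


@pytest.fixture(scope="session")
def roi_matcher():
    return match_roi_to_truth


def brute_force_huang(histogram):
    """Independent exhaustive-search oracle for the fuzzy-entropy threshold.

    Deliberately naive: loops over every candidate level and every gray
    level, recomputing class means and per-level Shannon fuzzy entropy.
    """
    hist = np.asarray(histogram, dtype=float)
    occupied = np.flatnonzero(hist > 0)
    g_min, g_max = occupied[0], occupied[-1]
    c = float(g_max - g_min)
    best_t, best_e = None, None
    # only occupied levels below the top can be the lowest-t argmin: an
    # unoccupied candidate induces the same partition as the occupied
    # level below it
    for t in occupied[:-1]:
        lo = [g for g in occupied if g <= t]
        hi = [g for g in occupied if g > t]
        if not lo or not hi:
            continue
        mu0 = sum(g * hist[g] for g in lo) / sum(hist[g] for g in lo)
        mu1 = sum(g * hist[g] for g in hi) / sum(hist[g] for g in hi)
        e = 0.0
        for g in occupied:
            mu = mu0 if g <= t else mu1
            m = 1.0 / (1.0 + abs(g - mu) / c)
            if 0.0 < m < 1.0:
                e += hist[g] * (-m * np.log(m) - (1 - m) * np.log(1 - m))
        if best_e is None or e < best_e - 1e-15:
            best_e, best_t = e, t
    return best_t


@pytest.fixture(scope="session")
def huang_oracle():
    return brute_force_huang
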