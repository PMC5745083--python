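import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from flymosaic import segmentation as seg
from flymosaic import synthetic
from flymosaic.segmentation import (AMBIGUOUS, RH3, RH4, CandidateRegion,
                                    MosaicCount, RetinaImage,
                                    SegmentationParams, classify_regions,
                                    count_mosaic, detect_boundaries,
                                    filter_regions, homomorphic_denoise,
                                    refine_contours, roi_mean_intensity,
                                    rough_segment, watershed_partition)


def gaussian_spot(shape, center, sigma, amplitude=1.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                              / (2 * sigma ** 2))


# ------------------------------------------------------------- homomorphic
def test_homomorphic_constant_image_stays_constant():
    out = homomorphic_denoise(np.full((40, 40), 3.0), cutoff=0.02,
                              gaussian_sigma=0.0)
    assert np.ptp(out) < 1e-6


def test_homomorphic_zero_cutoff_is_identity_up_to_blur():
    rng = np.random.default_rng(0)
    img = rng.uniform(0.5, 1.5, (30, 30))
    out = homomorphic_denoise(img, cutoff=0.0, gaussian_sigma=1.2)
    np.testing.assert_allclose(out, ndi.gaussian_filter(img, 1.2), rtol=1e-3,
                               atol=1e-3)


def test_homomorphic_reduces_background_cv():
    # background-only generator image with a strong illumination gradient
    cfg = synthetic.SimulationConfig(seed=3, n_rows=6, n_cols=6,
                                     on_fraction=0.0, illum_amplitude=0.8,
                                     noise_sd=0.0)
    image, _ = synthetic.generate_retina_image(cfg)
    # rh4 channel holds no spots: pure illumination-scaled background
    before = image.rh4
    after = homomorphic_denoise(before, cutoff=0.01, gaussian_sigma=0.0)
    cv = lambda a: a.std() / a.mean()
    assert cv(after) < cv(before)


def test_homomorphic_nonfinite_errors():
    bad = np.ones((5, 5))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        homomorphic_denoise(bad)


# ------------------------------------------------------------------ edges
def test_detect_boundaries_blank_image_empty():
    assert not detect_boundaries(np.zeros((30, 30)), 0.1, 0.2).any()


def test_detect_boundaries_bad_thresholds():
    with pytest.raises(ValueError):
        detect_boundaries(np.zeros((10, 10)), 0.3, 0.2)


def test_disk_contour_encloses_disk_area():
    shape, radius = (80, 80), 12
    rr, cc = np.mgrid[0:80, 0:80]
    disk = ((rr - 40) ** 2 + (cc - 40) ** 2 <= radius ** 2).astype(float)
    edges = detect_boundaries(ndi.gaussian_filter(disk, 1.0), 0.1, 0.3)
    regions = rough_segment(edges)
    assert len(regions) == 1
    assert regions[0].area == pytest.approx(math.pi * radius ** 2, rel=0.10)


# ---------------------------------------------------------------- hulls
def test_rough_segment_fills_c_shape():
    edges = np.zeros((30, 30), dtype=bool)
    edges[5:25, 5] = True    # left bar
    edges[5, 5:20] = True    # top bar
    edges[24, 5:20] = True   # bottom bar: C shape, open to the right
    regions = rough_segment(edges)
    assert len(regions) == 1
    hull = regions[0].mask
    assert hull[15, 12]  # interior of the concavity is filled


def test_rough_segment_candidate_count_near_truth():
    cfg = synthetic.SimulationConfig(seed=2)  # 210 spots
    image, truth = synthetic.generate_retina_image(cfg)
    combined = (homomorphic_denoise(image.rh3) + homomorphic_denoise(image.rh4))
    edges = detect_boundaries(combined, 0.08, 0.2)
    regions = rough_segment(edges)
    assert abs(len(regions) - truth.n_spots) <= 0.15 * truth.n_spots


# ------------------------------------------------------------ refinement
def test_refine_zero_iterations_identity():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5:10, 5:10] = True
    region = CandidateRegion(mask)
    out = refine_contours([region], np.random.default_rng(0).random((20, 20)),
                          contour_iterations=0)
    np.testing.assert_array_equal(out[0].mask, mask)


def test_refine_shrinks_oversized_hull_toward_spot():
    shape, sigma = (40, 40), 3.0
    channel = gaussian_spot(shape, (20, 20), sigma) + 0.02
    true_area = np.sum(channel > 0.5 + 0.02)  # FWHM-ish disk
    big = np.zeros(shape, dtype=bool)
    big[8:33, 8:33] = True  # much larger than the spot
    refined = refine_contours([CandidateRegion(big)], channel,
                              contour_iterations=30, max_dilation=2)[0]
    assert abs(refined.area - true_area) < abs(int(big.sum()) - true_area)


def test_refine_stays_within_dilation_bound():
    shape = (30, 30)
    channel = gaussian_spot(shape, (15, 15), 2.5) + 0.01
    mask = np.zeros(shape, dtype=bool)
    mask[12:19, 12:19] = True
    refined = refine_contours([CandidateRegion(mask)], channel,
                              contour_iterations=20, max_dilation=3)[0]
    from skimage.morphology import disk
    allowed = ndi.binary_dilation(mask, structure=disk(3))
    assert not (refined.mask & ~allowed).any()


# ------------------------------------------------------------- watershed
def two_spot_image(d=7):
    shape = (40, 40)
    c1, c2 = (20, 16), (20, 16 + d)
    ch = gaussian_spot(shape, c1, 2.5) + gaussian_spot(shape, c2, 2.5) + 0.01
    return RetinaImage(ch, np.full(shape, 0.01)), c1, c2


def test_watershed_splits_touching_spots():
    image, c1, c2 = two_spot_image()
    mask = image.rh3 > 0.15
    labels = watershed_partition(image, [CandidateRegion(mask)],
                                 min_seed_distance=4)
    l1, l2 = labels[c1], labels[c2]
    assert l1 != 0 and l2 != 0 and l1 != l2


def test_watershed_single_seed_single_region():
    shape = (30, 30)
    ch = gaussian_spot(shape, (15, 15), 3.0) + 0.01
    image = RetinaImage(ch, np.full(shape, 0.01))
    mask = ch > 0.2
    labels = watershed_partition(image, [CandidateRegion(mask)],
                                 min_seed_distance=25)
    assert set(np.unique(labels)) == {0, 1}


def test_watershed_no_regions_warns_empty():
    image = RetinaImage(np.ones((10, 10)), np.ones((10, 10)))
    labels = watershed_partition(image, [])
    assert not labels.any()


def test_watershed_labels_partition_foreground():
    image, _, _ = two_spot_image()
    mask = image.rh3 > 0.15
    labels = watershed_partition(image, [CandidateRegion(mask)])
    assert (labels[~mask] == 0).all()
    # by construction of a labeled raster, labels are disjoint; check the
    # foreground is fully assigned
    assert (labels[mask] > 0).all()


# -------------------------------------------------------------- filtering
def square_labels(*specs):
    """specs: (label, row, col, side) squares on a 100x100 canvas."""
    labels = np.zeros((100, 100), dtype=np.int32)
    for label, r, c, side in specs:
        labels[r:r + side, c:c + side] = label
    return labels


def test_filter_regions_area_boundaries():
    labels = square_labels((1, 10, 10, 3), (2, 50, 50, 4))  # areas 9, 16
    out = filter_regions(labels, min_area=10, max_area=100)
    assert 1 not in out
    assert 2 in out


def test_filter_regions_center_retained():
    labels = square_labels((1, 48, 48, 4))  # centroid ~ image center
    out = filter_regions(labels, 1, 1000, max_center_distance=0.01)
    assert 1 in out


def test_filter_regions_distance_excludes_corner():
    labels = square_labels((1, 0, 0, 4), (2, 48, 48, 4))
    out = filter_regions(labels, 1, 1000, max_center_distance=0.5)
    assert 1 not in out
    assert 2 in out


def test_filter_regions_monotone_and_relaxation():
    rng = np.random.default_rng(0)
    labels, _ = ndi.label(rng.random((60, 60)) > 0.7)
    n_before = len(np.unique(labels)) - 1
    strict = filter_regions(labels, 3, 20, 0.5)
    assert len(np.unique(strict)) - 1 <= n_before
    relaxed = filter_regions(labels, 1, labels.size, 1.0)
    np.testing.assert_array_equal(relaxed, labels)


# ---------------------------------------------------------- classification
def test_classify_bright_rh4_region():
    labels = square_labels((1, 10, 10, 5))
    image = RetinaImage(np.full((100, 100), 0.05),
                        np.where(labels == 1, 1.0, 0.05))
    calls = classify_regions(labels, image)
    assert calls[0].call == RH4


def test_classify_equal_means_ambiguous():
    labels = square_labels((1, 10, 10, 5))
    ch = np.where(labels == 1, 1.0, 0.05)
    calls = classify_regions(labels, RetinaImage(ch, ch.copy()),
                             ambiguity_margin=1e-6)
    assert calls[0].call == AMBIGUOUS


def test_classify_zero_denominator_names_channel():
    labels = square_labels((1, 10, 10, 5))
    image = RetinaImage(np.zeros((100, 100)), np.zeros((100, 100)))
    with pytest.raises(ValueError, match="rh3"):
        classify_regions(labels, image)


def test_classify_matches_brute_force_means():
    rng = np.random.default_rng(8)
    labels = square_labels((1, 5, 5, 6), (2, 40, 60, 7), (3, 70, 20, 5))
    image = RetinaImage(rng.random((100, 100)), rng.random((100, 100)))
    calls = {r.label: r for r in classify_regions(labels, image,
                                                  intensity_percentile=99.0)}
    pool = labels > 0
    p3 = np.percentile(image.rh3[pool], 99.0)
    p4 = np.percentile(image.rh4[pool], 99.0)
    n3 = max(p3, 0.2 * max(p3, p4))
    n4 = max(p4, 0.2 * max(p3, p4))
    for label in (1, 2, 3):
        mask = labels == label
        assert calls[label].mean_rh3 == image.rh3[mask].mean()
        assert calls[label].mean_rh4 == image.rh4[mask].mean()
        assert calls[label].norm_rh3 == calls[label].mean_rh3 / n3
        assert calls[label].norm_rh4 == calls[label].mean_rh4 / n4


def test_classify_accuracy_against_ground_truth(small_retina_config):
    image, truth = synthetic.generate_retina_image(small_retina_config)
    params = SegmentationParams()
    d3 = homomorphic_denoise(image.rh3)
    d4 = homomorphic_denoise(image.rh4)
    denoised = RetinaImage(d3, d4)
    edges = detect_boundaries(d3 + d4, params.canny_low, params.canny_high,
                              params.canny_sigma)
    regions = refine_contours(rough_segment(edges), d3 + d4,
                              params.contour_iterations)
    labels = watershed_partition(denoised, regions)
    labels = filter_regions(labels, params.min_area, params.max_area)
    calls = classify_regions(labels, denoised)
    # match each region to the nearest true spot
    correct = total = 0
    for region in calls:
        dists = np.linalg.norm(truth.centers - np.array(region.centroid),
                               axis=1)
        nearest = int(np.argmin(dists))
        if dists[nearest] > small_retina_config.spacing / 2:
            continue
        total += 1
        expected = RH4 if truth.identities[nearest] else RH3
        correct += region.call == expected
    assert total >= 0.8 * truth.n_spots
    assert correct / total >= 0.97


# ------------------------------------------------------------- end to end
def test_count_mosaic_all_off():
    cfg = synthetic.SimulationConfig(seed=5, n_rows=7, n_cols=8,
                                     on_fraction=0.0)
    image, _ = synthetic.generate_retina_image(cfg)
    count = count_mosaic(image)
    assert count.n_rh4 == 0
    assert count.pct_on == 0.0


def test_count_mosaic_deterministic(small_retina_config):
    image, _ = synthetic.generate_retina_image(small_retina_config)
    c1 = count_mosaic(image)
    c2 = count_mosaic(image)
    assert (c1.n_rh3, c1.n_rh4, c1.n_ambiguous) == \
        (c2.n_rh3, c2.n_rh4, c2.n_ambiguous)


def test_count_mosaic_recovers_ground_truth(small_retina_config):
    image, truth = synthetic.generate_retina_image(small_retina_config)
    count = count_mosaic(image)
    assert abs(count.pct_on - truth.pct_on_true) <= 3.0


def test_mosaic_count_floor_and_bounds():
    count = MosaicCount(40, 80, 2)
    assert count.pct_on == pytest.approx(100 * 80 / 120)
    assert count.meets_floor(100)
    assert not MosaicCount(30, 40).meets_floor(100)
    with pytest.raises(ValueError):
        MosaicCount(0, 0).pct_on


# -------------------------------------------------------------------- ROI
def test_roi_constant_image():
    means = roi_mean_intensity(np.full((30, 30), 7.0), [(10, 10), (20, 5)],
                               radius=3)
    assert means == [7.0, 7.0]


def test_roi_mean_between_background_and_amplitude():
    ch = gaussian_spot((40, 40), (20, 20), 3.0, amplitude=2.0) + 0.1
    [mean] = roi_mean_intensity(ch, [(20, 20)], radius=4)
    assert 0.1 < mean < 2.1


def test_roi_two_spots_exceed_one_spot_direct_sum_oracle():
    one = gaussian_spot((50, 50), (25, 20), 2.0) + 0.05
    two = one + gaussian_spot((50, 50), (25, 30), 2.0)
    center, radius = (25, 25), 12
    [m_one] = roi_mean_intensity(one, [center], radius)
    [m_two] = roi_mean_intensity(two, [center], radius)
    rr, cc = np.mgrid[0:50, 0:50]
    mask = (rr - 25) ** 2 + (cc - 25) ** 2 <= radius ** 2
    assert m_one == pytest.approx(one[mask].mean())
    assert m_two == pytest.approx(two[mask].mean())
    assert m_two > m_one


def test_roi_outside_image_errors():
    with pytest.raises(ValueError):
        roi_mean_intensity(np.ones((20, 20)), [(100, 100)], radius=2)


def test_roi_order_preserved():
    ch = np.arange(400, dtype=float).reshape(20, 20)
    means = roi_mean_intensity(ch, [(15, 15), (2, 2)], radius=1)
    assert means[0] > means[1]


# ------------------------------------------------------------- parameters
def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(canny_low=0.5, canny_high=0.2)
    with pytest.raises(ValueError):
        SegmentationParams(min_area=100, max_area=10)
    with pytest.raises(ValueError):
        SegmentationParams(max_center_distance=1.5)


def test_retina_image_validation():
    with pytest.raises(ValueError):
        RetinaImage(np.ones((5, 5)), np.ones((6, 5)))
    with pytest.raises(ValueError):
        RetinaImage(-np.ones((5, 5)), np.ones((5, 5)))
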