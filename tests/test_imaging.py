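"""Background subtraction, binarization, density binning and colocalization."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

import spnatlas as sa


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

def test_tophat_of_constant_image_is_zero():
    img = np.full((120, 120), 77, dtype=np.uint8)
    out = sa.subtract_background(img, radius=5)
    assert not out.any()


def test_small_bright_feature_survives_tophat():
    img = np.zeros((120, 120), dtype=np.uint8)
    img[60, 60] = 200
    out = sa.subtract_background(img, radius=5)
    assert out[60, 60] == 200


def test_tophat_matches_min_max_filter_oracle(rng):
    """Opening = erosion then dilation; oracle built from min/max filters."""
    yy, xx = np.mgrid[0:100, 0:100]
    gradient = (xx * 0.8).astype(np.uint8)
    img = gradient.copy()
    img[40:44, 50:54] = 220  # blob over a smooth background
    selem = disk(7).astype(bool)
    eroded = ndimage.minimum_filter(img, footprint=selem, mode="nearest")
    opened = ndimage.maximum_filter(eroded, footprint=selem, mode="nearest")
    oracle = np.clip(img.astype(int) - opened.astype(int), 0, 255)
    out = sa.subtract_background(img, radius=7)
    interior = (slice(10, 90), slice(10, 90))  # border modes differ by design
    np.testing.assert_allclose(out[interior].astype(int),
                               oracle[interior].astype(int), atol=1)


def test_oversized_structuring_element_rejected():
    with pytest.raises(ValueError):
        sa.subtract_background(np.zeros((100, 100), dtype=np.uint8), radius=60)


# ---------------------------------------------------------------------------
# binarization and component cleaning
# ---------------------------------------------------------------------------

def test_threshold_is_strict():
    img = np.full((50, 50), 119, dtype=np.uint8)
    assert not sa.binarize_and_clean(img).any()
    img121 = np.full((50, 50), 121, dtype=np.uint8)
    assert sa.binarize_and_clean(img121).all()


def test_two_pixel_component_removed_three_kept():
    img = np.zeros((30, 30), dtype=np.uint8)
    img[5, 5:7] = 200                  # 2-pixel run
    img[20, 10] = img[20, 11] = img[21, 10] = 200  # 3-pixel L
    out = sa.binarize_and_clean(img)
    assert not out[5, 5:7].any()
    assert out[20, 10] and out[20, 11] and out[21, 10]


def _flood_fill_components(mask, connectivity=2):
    """Brute-force BFS labeling oracle."""
    if connectivity == 2:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack, comp = [(sy, sx)], []
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


@pytest.mark.parametrize("connectivity", [1, 2])
def test_cleaning_matches_flood_fill_oracle(rng, connectivity):
    img = (rng.random((64, 64)) < 0.25).astype(np.uint8) * 200
    out = sa.binarize_and_clean(img, connectivity=connectivity)
    expected = np.zeros((64, 64), dtype=bool)
    for comp in _flood_fill_components(img > 120, connectivity):
        if len(comp) >= 3:
            for y, x in comp:
                expected[y, x] = True
    np.testing.assert_array_equal(out, expected)


# ---------------------------------------------------------------------------
# density grid
# ---------------------------------------------------------------------------

def test_empty_mask_gives_zero_grids():
    g = sa.bin_and_smooth(np.zeros((100, 100), dtype=bool))
    assert not g.bin_counts.any()
    assert not g.smoothed.any()


def test_full_bin_counts_400():
    mask = np.zeros((100, 100), dtype=bool)
    mask[20:40, 40:60] = True
    g = sa.bin_and_smooth(mask, bin_px=20)
    assert g.bin_counts[1, 2] == 400


def test_bin_count_conservation_exact(rng):
    mask = rng.random((137, 211)) < 0.3  # non-multiple dimensions
    g = sa.bin_and_smooth(mask)
    assert g.bin_counts.sum() == mask.sum()


def test_smoothing_preserves_interior_mass():
    counts_mask = np.zeros((200, 200), dtype=bool)
    counts_mask[80:120, 80:120] = True  # mass well inside the grid
    g = sa.bin_and_smooth(counts_mask, bin_px=20, smooth_px=100)
    assert abs(g.smoothed.sum() - g.bin_counts.sum()) < 1e-9


def test_smooth_unit_selectable():
    mask = np.zeros((200, 200), dtype=bool)
    mask[100:110, 100:110] = True
    by_px = sa.bin_and_smooth(mask, smooth_px=100, smooth_unit="pixels")
    by_bins = sa.bin_and_smooth(mask, smooth_px=5, smooth_unit="bins")
    np.testing.assert_allclose(by_px.smoothed, by_bins.smoothed, atol=1e-12)


def _gaussian_grid(sigma_bins=4.0, size=41):
    yy, xx = np.mgrid[0:size, 0:size] - size // 2
    s = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma_bins ** 2))
    return sa.DensityGrid(bin_counts=np.round(s * 100).astype(np.int64),
                          smoothed=s, bin_px=20)


def test_central_peak_contours_are_nested_and_closed():
    g = _gaussian_grid()
    contours = sa.contour_from_density(g, n_levels=4)
    assert len(contours) == 4
    for level, polys in contours.items():
        assert len(polys) == 1
        p = polys[0] / g.bin_px
        np.testing.assert_allclose(p[0], p[-1], atol=1e-9)  # closed


def test_two_separated_peaks_give_disjoint_high_contours():
    yy, xx = np.mgrid[0:60, 0:60]
    s = np.exp(-((yy - 15) ** 2 + (xx - 15) ** 2) / 18.0) \
        + np.exp(-((yy - 45) ** 2 + (xx - 45) ** 2) / 18.0)
    g = sa.DensityGrid(bin_counts=np.round(s).astype(np.int64), smoothed=s,
                       bin_px=20)
    contours = sa.contour_from_density(g, n_levels=4)
    top = contours[max(contours)]
    assert len(top) == 2


def test_gaussian_half_max_contour_area_matches_closed_form():
    sigma = 5.0
    g = _gaussian_grid(sigma_bins=sigma, size=61)
    polys = sa.contour_from_density(g, n_levels=1)  # single level at max/2
    (level, (poly,)) = next(iter(polys.items()))
    assert level == pytest.approx(g.smoothed.max() / 2)
    p = poly / g.bin_px  # back to bin units
    x, y = p[:, 1], p[:, 0]
    area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    fwhm = 2 * sigma * np.sqrt(2 * np.log(2))
    assert abs(area - np.pi * (fwhm / 2) ** 2) / (np.pi * (fwhm / 2) ** 2) < 0.1


def test_flat_grid_warns_no_contours(caplog):
    g = sa.DensityGrid(bin_counts=np.zeros((5, 5), dtype=np.int64),
                       smoothed=np.zeros((5, 5)), bin_px=20)
    with caplog.at_level("WARNING"):
        assert sa.contour_from_density(g) == {}


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def _mask_image(values_ch2, n=100, side=10):
    """n disjoint square masks; ch1 always bright, ch2 per-mask pattern."""
    cols = 10
    h = ((n + cols - 1) // cols) * (side + 2) + 2
    w = cols * (side + 2) + 2
    ch1 = np.zeros((h, w), dtype=np.uint8)
    ch2 = np.zeros((h, w), dtype=np.uint8)
    masks = np.zeros((h, w), dtype=np.int32)
    for i in range(n):
        r, c = divmod(i, cols)
        y, x = 2 + r * (side + 2), 2 + c * (side + 2)
        ch1[y:y + side, x:x + side] = 200
        ch2[y:y + side, x:x + side] = values_ch2[i]
        masks[y:y + side, x:x + side] = i + 1
    return ch1, ch2, masks


def test_colocalization_boundary_inclusive():
    # mask of 100 px with exactly 65 vs 64 co-intense pixels
    ch1 = np.zeros((20, 20), dtype=np.uint8)
    ch2 = np.zeros((20, 20), dtype=np.uint8)
    masks = np.zeros((20, 20), dtype=np.int32)
    ch1[:10, :10] = 200
    masks[:10, :10] = 1
    flat = ch2[:10, :10].ravel()
    flat[:65] = 200
    ch2[:10, :10] = flat.reshape(10, 10)
    (call,) = sa.call_colocalization(ch1, ch2, masks, thresholds=(100, 100))
    assert call.fraction == pytest.approx(0.65)
    assert call.positive
    ch2[:10, :10] = 0
    flat = ch2[:10, :10].ravel()
    flat[:64] = 200
    ch2[:10, :10] = flat.reshape(10, 10)
    (call,) = sa.call_colocalization(ch1, ch2, masks, thresholds=(100, 100))
    assert not call.positive


def test_planted_colocalization_fraction_recovered(rng):
    n = 100
    pos = rng.random(n) < 0.5
    ch2_vals = np.where(pos, 200, 10)
    ch1, ch2, masks = _mask_image(ch2_vals, n=n)
    calls = sa.call_colocalization(ch1, ch2, masks, thresholds=(100, 100))
    called = np.array([c.positive for c in sorted(calls, key=lambda c: c.mask_id)])
    np.testing.assert_array_equal(called, pos)
    assert abs(called.sum() - 50) < 3 * np.sqrt(n * 0.25)


def test_calls_invariant_to_monotone_rescale_with_quantile_thresholds(rng):
    n = 60
    pos = rng.random(n) < 0.4
    ch1, ch2, masks = _mask_image(np.where(pos, 200, 10), n=n)

    def quantile_thresholds(c1, c2, q=0.8):
        return (float(np.quantile(c1, q)), float(np.quantile(c2, q)))

    base = sa.call_colocalization(ch1, ch2, masks,
                                  thresholds=quantile_thresholds(ch1, ch2))
    f = lambda img: np.sqrt(img.astype(float)) * 10  # strictly monotone
    r1, r2 = f(ch1), f(ch2)
    rescaled = sa.call_colocalization(r1, r2, masks,
                                      thresholds=quantile_thresholds(r1, r2))
    assert [c.positive for c in base] == [c.positive for c in rescaled]


def test_calls_invariant_to_mask_order(rng):
    n = 30
    ch1, ch2, masks = _mask_image(np.where(rng.random(n) < 0.5, 200, 10), n=n)
    base = {c.mask_id: c.positive
            for c in sa.call_colocalization(ch1, ch2, masks, thresholds=(100, 100))}
    # relabel masks in reverse order
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:] = np.arange(n, 0, -1)
    relabeled = remap[masks]
    new = {c.mask_id: c.positive
           for c in sa.call_colocalization(ch1, ch2, relabeled,
                                           thresholds=(100, 100))}
    for old_id, positive in base.items():
        assert new[n + 1 - old_id] == positive


def test_missing_expected_mask_rejected():
    ch1, ch2, masks = _mask_image([200] * 4, n=4)
    with pytest.raises(ValueError, match="mask 9"):
        sa.call_colocalization(ch1, ch2, masks, thresholds=(100, 100),
                               expected_ids=[1, 2, 3, 4, 9])


def test_soma_area_scales_with_pixel_size():
    ch1, ch2, masks = _mask_image([200] * 2, n=2)
    calls = sa.call_colocalization(ch1, ch2, masks, thresholds=(100, 100),
                                   pixel_size_um=0.5)
    for c in calls:
        assert c.soma_area_px == 100
        assert c.soma_area_um2 == pytest.approx(25.0)
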