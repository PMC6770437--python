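"""Segmentation chain: per-step contracts and end-to-end recovery."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from fetalbrain import (PhantomSpec, SegmentationError, StructuringElement,
                        ThresholdParams, generate_phantom, segment_brain)
from fetalbrain.evaluation import segmentation_scores
from fetalbrain.segmentation import (adaptive_threshold, apply_mask,
                                     area_select, clear_border,
                                     extract_minor_roi, morph_close,
                                     morph_open, trace_boundaries,
                                     upper_right_quadrant, watershed_split)

DISK1 = StructuringElement("disk", 1)


def brute_erode(mask, fp):
    """Double-loop erosion oracle; outside the image counts as background."""
    r = fp.shape[0] // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not fp[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    inside = 0 <= ii < mask.shape[0] and 0 <= jj < mask.shape[1]
                    if not (inside and mask[ii, jj]):
                        ok = False
            out[i, j] = ok
    return out


def brute_dilate(mask, fp):
    r = fp.shape[0] // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not fp[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < mask.shape[0] and 0 <= jj < mask.shape[1] \
                            and mask[ii, jj]:
                        hit = True
            out[i, j] = hit
    return out


# ------------------------------------------------------------------ threshold

def test_threshold_constant_image_all_background():
    img = np.full((16, 16), 100.0)
    mask = adaptive_threshold(img, ThresholdParams(window=5, offset=1.0))
    assert not mask.any()


def test_threshold_step_image_splits_at_global_mean():
    """Full-size window: every pixel is compared against the global mean."""
    img = np.zeros((17, 17))
    img[:, 9:] = 255.0
    mask = adaptive_threshold(img, ThresholdParams(window=17, offset=0.0))
    assert mask[:, 9:].all() and not mask[:, :9].any()


def test_threshold_negative_offset_all_foreground():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, (20, 20)).astype(float)
    mask = adaptive_threshold(img, ThresholdParams(window=5, offset=-255.0))
    assert mask.all()


def test_threshold_window_too_large_rejected():
    with pytest.raises(ValueError, match="window"):
        adaptive_threshold(np.zeros((8, 8)), ThresholdParams(window=9))
    with pytest.raises(ValueError):
        ThresholdParams(window=4)  # even


# ----------------------------------------------------------------- morphology

def test_open_removes_isolated_pixel():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    assert not morph_open(mask, DISK1).any()


def test_open_solid_square_matches_bruteforce_oracle():
    mask = np.zeros((11, 11), dtype=bool)
    mask[3:8, 3:8] = True
    fp = DISK1.footprint()
    expect = brute_dilate(brute_erode(mask, fp), fp)
    assert np.array_equal(morph_open(mask, DISK1), expect)
    # with a full 3x3 square element the solid square survives intact
    square = StructuringElement("square", 1)
    assert np.array_equal(morph_open(mask, square), mask)


def test_close_fills_hole_and_merges_near_squares():
    holed = np.zeros((9, 9), dtype=bool)
    holed[1:8, 1:8] = True
    holed[4, 4] = False
    assert morph_close(holed, DISK1)[1:8, 1:8].all()

    two = np.zeros((9, 12), dtype=bool)
    two[2:7, 2:5] = True
    two[2:7, 6:9] = True  # 1-px gap
    fp = DISK1.footprint()
    expect = brute_erode(brute_dilate(two, fp), fp)
    got = morph_close(two, DISK1)
    assert np.array_equal(got, expect)
    _, n = ndi.label(got)
    assert n == 1


def test_open_close_empty_mask_noop():
    empty = np.zeros((6, 6), dtype=bool)
    assert not morph_open(empty, DISK1).any()
    assert not morph_close(empty, DISK1).any()


def test_close_warns_on_mismatched_se():
    mask = np.ones((5, 5), dtype=bool)
    with pytest.warns(UserWarning, match="SE"):
        morph_close(mask, StructuringElement("disk", 2), opening_se=DISK1)


@pytest.mark.parametrize("radius", [1, 2])
def test_open_close_idempotent_on_random_masks(radius):
    se = StructuringElement("disk", radius)
    rng = np.random.default_rng(42)
    for _ in range(100):
        mask = rng.random((32, 32)) < 0.45
        opened = morph_open(mask, se)
        assert np.array_equal(morph_open(opened, se), opened)
        closed = morph_close(mask, se)
        assert np.array_equal(morph_close(closed, se), closed)


def test_closing_is_dual_of_opening_on_complement():
    """closing(A) == ~opening(~A) away from the frame (outside-is-0 rule)."""
    se = StructuringElement("disk", 1)
    rng = np.random.default_rng(7)
    for _ in range(100):
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:-2, 2:-2] = rng.random((28, 28)) < 0.5
        inner = np.s_[2:-2, 2:-2]
        lhs = morph_close(mask, se)
        rhs = ~morph_open(~mask, se)
        assert np.array_equal(lhs[inner], rhs[inner])


# --------------------------------------------------------------- clear_border

def test_clear_border_keeps_interior_components():
    mask = np.zeros((10, 10), dtype=bool)
    mask[0:3, 0:3] = True  # corner
    mask[5:8, 5:8] = True  # interior
    out = clear_border(mask)
    assert out[5:8, 5:8].all() and not out[0:3, 0:3].any()


def test_clear_border_identity_when_all_interior():
    mask = np.zeros((10, 10), dtype=bool)
    mask[4:7, 4:7] = True
    assert np.array_equal(clear_border(mask), mask)


def test_clear_border_removes_bridged_component_8conn():
    mask = np.zeros((10, 10), dtype=bool)
    mask[4:7, 4:7] = True
    # diagonal 1-px chain to the border: 8-connected to the blob
    mask[3, 3] = mask[2, 2] = mask[1, 1] = mask[0, 0] = True
    assert not clear_border(mask).any()


# ----------------------------------------------------------- trace_boundaries

def test_trace_filled_square_one_parent_no_children():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:8, 2:8] = True
    h = trace_boundaries(mask)
    assert len(h.parents) == 1 and len(h.children) == 0
    assert np.array_equal(h.region_image, mask)


def test_trace_square_with_hole_links_child():
    mask = np.zeros((12, 12), dtype=bool)
    mask[2:10, 2:10] = True
    mask[5:7, 5:7] = False
    h = trace_boundaries(mask)
    assert len(h.parents) == 1 and len(h.children) == 1
    assert h.children[0].parent == 0
    assert h.region_image[5:7, 5:7].all()  # hole filled in region image


def test_trace_two_squares_sorted_by_area():
    mask = np.zeros((20, 20), dtype=bool)
    mask[1:4, 1:4] = True  # small
    mask[6:16, 6:16] = True  # big, holed
    mask[10 - 1:11, 10 - 1:11] = False
    h = trace_boundaries(mask)
    assert len(h.parents) == 2 and len(h.children) == 1
    assert h.parents[0].area > h.parents[1].area
    assert h.children[0].parent == 0  # hole belongs to the big square


# ------------------------------------------------------------------ watershed

def test_watershed_single_convex_blob_one_region():
    rr, cc = np.mgrid[0:30, 0:30]
    mask = (rr - 15) ** 2 + (cc - 15) ** 2 <= 100
    labels = watershed_split(mask, h=1.0)
    assert labels.max() == 1


def test_watershed_splits_two_overlapping_disks():
    rr, cc = np.mgrid[0:40, 0:60]
    d1 = (rr - 20) ** 2 + (cc - 22) ** 2 <= 100
    d2 = (rr - 20) ** 2 + (cc - 37) ** 2 <= 100
    mask = d1 | d2
    labels = watershed_split(mask, h=1.0)
    assert labels.max() == 2
    # oracle: removing ridge pixels leaves two 4-connected components
    _, n = ndi.label(mask & (labels > 0),
                     structure=ndi.generate_binary_structure(2, 1))
    assert n == 2


def test_watershed_conserves_foreground_pixels():
    rr, cc = np.mgrid[0:40, 0:60]
    mask = ((rr - 20) ** 2 + (cc - 22) ** 2 <= 100) | \
           ((rr - 20) ** 2 + (cc - 37) ** 2 <= 100)
    labels = watershed_split(mask, h=1.0)
    ridge = mask & (labels == 0)
    assert (labels > 0).sum() + ridge.sum() == mask.sum()


def test_watershed_empty_mask_empty_labels():
    assert watershed_split(np.zeros((5, 5), dtype=bool)).max() == 0


# ---------------------------------------------------------------- area select

def test_area_select_largest_and_tie_break():
    labels = np.zeros((10, 10), dtype=int)
    labels[0:5, 0:5] = 1  # 25 px
    labels[6:9, 6:9] = 2  # 9 px
    assert np.array_equal(area_select(labels), labels == 1)

    tie = np.zeros((10, 10), dtype=int)
    tie[0:2, 0:2] = 2
    tie[5:7, 5:7] = 1  # equal areas: keep lowest label
    assert np.array_equal(area_select(tie), tie == 1)

    single = np.zeros((5, 5), dtype=int)
    single[1:3, 1:3] = 1
    assert np.array_equal(area_select(single), single == 1)

    with pytest.raises(ValueError, match="no labelled regions"):
        area_select(np.zeros((5, 5), dtype=int))


def test_area_select_conserves_max_region_area():
    rng = np.random.default_rng(3)
    labels, _ = ndi.label(rng.random((32, 32)) < 0.4)
    out = area_select(labels)
    counts = np.bincount(labels.ravel())
    assert out.sum() == counts[1:].max()


# ----------------------------------------------------------------- apply_mask

def test_apply_mask_examples():
    img = np.arange(16.0).reshape(4, 4)
    assert np.array_equal(apply_mask(img, np.ones((4, 4), bool)), img)
    assert not apply_mask(img, np.zeros((4, 4), bool)).any()
    checker = (np.indices((4, 4)).sum(axis=0) % 2).astype(bool)
    assert np.array_equal(apply_mask(img, checker), img * checker)
    with pytest.raises(ValueError, match="shape"):
        apply_mask(img, np.ones((3, 3), bool))


# ------------------------------------------------------------------ minor ROI

def test_upper_right_quadrant_arithmetic():
    assert upper_right_quadrant((10, 10, 100, 100)) == (10, 60, 50, 50)


def test_manual_box_equal_to_bbox_reproduces_whole_crop():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 255, (64, 64)).astype(float)
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:50, 12:52] = True
    seg = extract_minor_roi(img, mask, mode="manual", box=(10, 12, 40, 40),
                            roi_size=40)
    assert np.allclose(seg.minor_roi, img[10:50, 12:52])


def test_auto_roi_contained_in_bbox_for_random_masks():
    rng = np.random.default_rng(2)
    for _ in range(20):
        mask = np.zeros((64, 64), dtype=bool)
        r0, c0 = rng.integers(0, 30, 2)
        h, w = rng.integers(8, 30, 2)
        mask[r0:r0 + h, c0:c0 + w] = True
        seg = extract_minor_roi(np.zeros((64, 64)), mask, mode="auto")
        rr, cc, hh, ww = seg.roi_box
        assert rr >= r0 and cc >= c0
        assert rr + hh <= r0 + h and cc + ww <= c0 + w


def test_minor_roi_box_validation():
    img = np.zeros((32, 32))
    mask = np.zeros((32, 32), dtype=bool)
    mask[8:20, 8:20] = True
    with pytest.raises(ValueError, match="outside"):
        extract_minor_roi(img, mask, mode="manual", box=(30, 30, 10, 10))
    with pytest.raises(ValueError, match="empty"):
        extract_minor_roi(img, np.zeros_like(mask), mode="auto")


# ----------------------------------------------------------------- end-to-end

def test_segment_phantom_recovers_ground_truth(healthy_phantom):
    seg = segment_brain(healthy_phantom.image)
    sc = segmentation_scores(seg.brain_mask, healthy_phantom.brain_mask)
    assert sc.dice >= 0.9
    assert set(seg.intermediates) >= {"binary", "open", "clear", "close",
                                      "region", "watershed", "abs"}


def test_segment_insensitive_to_maternal_ring(healthy_phantom):
    """Suppressing everything outside the head leaves the brain mask alone."""
    img = healthy_phantom.image.astype(float)
    far = ~ndi.binary_dilation(healthy_phantom.brain_mask, iterations=8)
    stripped = np.where(far, 15.0, img)  # flatten maternal band to background
    m1 = segment_brain(img).brain_mask
    m2 = segment_brain(stripped).brain_mask
    rows = np.flatnonzero(healthy_phantom.brain_mask.any(axis=1))
    cols = np.flatnonzero(healthy_phantom.brain_mask.any(axis=0))
    bbox = np.s_[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    assert np.array_equal(m1[bbox], m2[bbox])


def test_all_zero_image_fails_at_threshold_step():
    with pytest.raises(SegmentationError) as err:
        segment_brain(np.zeros((128, 128)))
    assert err.value.step == "adaptive_threshold"
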