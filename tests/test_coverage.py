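"""Segmentation and the coverage-ratio statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meptrace.coverage import (
    BinaryMask,
    EmptyMEPMaskError,
    FilterSpec,
    ThresholdSpec,
    coverage_profile,
    coverage_ratio,
    fill_holes,
    invert_for_display,
    segment_mep_signal,
    segment_tracer_region,
)
from meptrace.synth.imaging import SectionImage


# ---------------------------------------------------------------- oracles

def flood_fill_oracle(mask: np.ndarray) -> np.ndarray:
    """Reference hole filling: BFS of background from the border,
    4-connectivity; everything not reached becomes foreground."""
    h, w = mask.shape
    reachable = np.zeros_like(mask, dtype=bool)
    stack = [(r, c) for r in range(h) for c in range(w)
             if (r in (0, h - 1) or c in (0, w - 1)) and not mask[r, c]]
    for rc in stack:
        reachable[rc] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                    and not reachable[rr, cc]:
                reachable[rr, cc] = True
                stack.append((rr, cc))
    return mask | ~reachable


def loop_coverage_oracle(mep: np.ndarray, ctb: np.ndarray) -> float:
    n_mep = n_in = 0
    for r in range(mep.shape[0]):
        for c in range(mep.shape[1]):
            if mep[r, c]:
                n_mep += 1
                if ctb[r, c]:
                    n_in += 1
    return n_in / n_mep


def median3_oracle(img: np.ndarray) -> np.ndarray:
    """Reference 3×3 median with edge replication (as scipy 'reflect')."""
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    vals.append(img[rr, cc])
            out[r, c] = sorted(vals)[4]
    return out


# ---------------------------------------------------------- segmentation

def test_ring_with_hole_fills_to_disk():
    img = np.zeros((8, 8))
    img[2:6, 2:6] = 100.0  # bright square ...
    img[3:5, 3:5] = 5.0  # ... enclosing a dark 2x2 centre
    mask = segment_tracer_region(img, ThresholdSpec.manual(50.0))
    expected = flood_fill_oracle(img > 50.0)
    np.testing.assert_array_equal(mask.pixels, expected)
    assert mask.pixels[3:5, 3:5].all()  # the hole became foreground


def test_all_zero_image_gives_empty_mask():
    img = np.zeros((6, 6))
    assert segment_tracer_region(img, ThresholdSpec.manual(0.5)).count == 0
    with pytest.warns(UserWarning, match="constant"):
        assert segment_tracer_region(img, ThresholdSpec.auto()).count == 0
    with pytest.warns(UserWarning, match="constant"):
        assert segment_mep_signal(img, FilterSpec("none"),
                                  ThresholdSpec.auto()).count == 0


def test_binary_image_without_holes_is_identity():
    rng = np.random.default_rng(0)
    img = (rng.random((12, 12)) < 0.2).astype(float)
    img = np.where(fill_holes(img > 0.5), 1.0, img)  # remove enclosed holes
    mask = segment_tracer_region(img, ThresholdSpec.manual(0.5))
    np.testing.assert_array_equal(mask.pixels, img > 0.5)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_hole_fill_matches_oracle_and_keeps_foreground(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((10, 10)) < 0.4
    filled = fill_holes(mask)
    np.testing.assert_array_equal(filled, flood_fill_oracle(mask))
    assert (filled & mask).sum() == mask.sum()  # never deletes foreground


def test_median_filter_removes_impulses_keeps_puncta():
    img = np.zeros((20, 20))
    puncta_at = [(3, 3), (10, 14), (16, 6)]
    for r, c in puncta_at:
        img[r - 1:r + 2, c - 1:c + 2] = 100.0  # 3x3 puncta
    impulses_at = [(1, 17), (7, 7), (18, 18)]
    for r, c in impulses_at:
        img[r, c] = 255.0  # isolated hot pixels
    mask = segment_mep_signal(img, FilterSpec("median", 3),
                              ThresholdSpec.manual(50.0))
    np.testing.assert_array_equal(mask.pixels, median3_oracle(img) > 50.0)
    for r, c in impulses_at:
        assert not mask.pixels[r, c]
    for r, c in puncta_at:
        assert mask.pixels[r, c]  # punctum core survives


def test_manual_threshold_above_maximum_gives_empty_mask():
    img = np.zeros((5, 5))
    img[2, 2] = 10.0
    assert segment_mep_signal(img, FilterSpec("none"),
                              ThresholdSpec.manual(11.0)).count == 0


# ------------------------------------------------------------- coverage

def test_coverage_ratio_direct_counts():
    mep = np.zeros((5, 5), dtype=bool)
    mep.flat[:10] = True
    ctb = np.zeros((5, 5), dtype=bool)
    ctb.flat[:7] = True
    assert coverage_ratio(mep, ctb) == pytest.approx(0.7)


def test_coverage_bounds_superset_and_disjoint():
    mep = np.zeros((4, 4), dtype=bool)
    mep[1:3, 1:3] = True
    assert coverage_ratio(mep, np.ones_like(mep)) == 1.0
    assert coverage_ratio(mep, np.zeros_like(mep)) == 0.0


def test_coverage_errors():
    empty = np.zeros((3, 3), dtype=bool)
    some = ~empty
    with pytest.raises(EmptyMEPMaskError):
        coverage_ratio(empty, some)
    with pytest.raises(ValueError, match="shape"):
        coverage_ratio(some, np.zeros((2, 2), dtype=bool))


def test_coverage_matches_loop_oracle_on_random_masks():
    rng = np.random.default_rng(12)
    for _ in range(20):
        mep = rng.random((64, 64)) < 0.3
        if not mep.any():
            continue
        ctb = rng.random((64, 64)) < 0.5
        assert coverage_ratio(mep, ctb) == pytest.approx(
            loop_coverage_oracle(mep, ctb))


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_growing_ctb_never_decreases_coverage(seed):
    rng = np.random.default_rng(seed)
    mep = rng.random((16, 16)) < 0.3
    if not mep.any():
        return
    ctb = rng.random((16, 16)) < 0.4
    grown = ctb | (rng.random((16, 16)) < 0.3)
    assert coverage_ratio(mep, grown) >= coverage_ratio(mep, ctb)


def test_display_inversion_changes_no_count():
    rng = np.random.default_rng(5)
    mask = BinaryMask((rng.random((8, 8)) < 0.5))
    inv = invert_for_display(mask)
    assert mask.count == (~inv).sum()
    np.testing.assert_array_equal(~invert_for_display(inv), inv)


# -------------------------------------------------------------- profile

def _section(depth, mep_fg, overlap_fg):
    """Binary-valued section with known MEP and tracer foregrounds."""
    mep = np.zeros((10, 10))
    tracer = np.zeros((10, 10))
    mep.flat[:mep_fg] = 100.0
    tracer.flat[:overlap_fg] = 100.0
    return SectionImage(depth_um=depth,
                        channels={"tracer": tracer, "mep": mep},
                        pixel_size_um=10.0)


def test_profile_unweighted_mean_over_depths():
    sections = [_section(100.0, 10, 4), _section(200.0, 10, 6)]
    res = coverage_profile(sections, FilterSpec("none"),
                           ThresholdSpec.manual(50.0))
    assert [d.coverage for d in res.per_depth] == [0.4, 0.6]
    assert res.mean_coverage == pytest.approx(0.5)
    assert res.per_depth[0].mep_pixels == 10
    assert res.per_depth[0].mep_pixels_in_ctb == 4

    single = coverage_profile([_section(50.0, 10, 4)], FilterSpec("none"),
                              ThresholdSpec.manual(50.0))
    assert single.mean_coverage == pytest.approx(0.4)


def test_profile_excludes_empty_mep_sections():
    sections = [_section(100.0, 10, 5), _section(200.0, 0, 0)]
    res = coverage_profile(sections, FilterSpec("none"),
                           ThresholdSpec.manual(50.0))
    assert np.isnan(res.per_depth[1].coverage)
    assert res.mean_coverage == pytest.approx(0.5)


def test_profile_rejects_bad_input():
    with pytest.raises(ValueError, match="at least one"):
        coverage_profile([])
    s = _section(100.0, 5, 2)
    with pytest.raises(ValueError, match="distinct"):
        coverage_profile([s, s])
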