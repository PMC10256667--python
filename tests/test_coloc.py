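import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipnet import (
    MultiChannelImage,
    ThresholdPair,
    auto_threshold,
    coloc_pixel_map,
    coloc_report,
    cytoplasm_intensity,
    fold_change,
    line_profile,
    pearson_correlation,
    regression_fit,
)
from lipnet.coloc import below_set_correlation, threshold_candidates
from lipnet.exceptions import DegenerateFitError, DegenerateInputError


def _plane(values):
    return np.asarray(values, dtype=np.float64).reshape(2, -1)


def _closed_form_pearson(a, b):
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    da, db = a - a.mean(), b - b.mean()
    return (da * db).sum() / math.sqrt((da * da).sum() * (db * db).sum())


def _closed_form_ols(a, b):
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    da = a - a.mean()
    slope = (da * (b - b.mean())).sum() / (da * da).sum()
    return slope, b.mean() - slope * a.mean()


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
        ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),
        ([0, 1, 2, 3], [1, 0, 3, 2], 0.6),
    ],
)
def test_pearson_worked_examples(a, b, expected):
    assert pearson_correlation(_plane(a), _plane(b)) == pytest.approx(expected, abs=1e-12)


def test_pearson_undefined_and_preconditions():
    assert pearson_correlation(_plane([5, 5, 5, 5]), _plane([1, 2, 3, 4])) is None
    with pytest.raises(ValueError):
        pearson_correlation(np.array([[1.0]]), np.array([[2.0]]))


@pytest.mark.parametrize(
    "a, b, slope, intercept",
    [
        ([1, 2, 3, 4], [2, 4, 6, 8], 2.0, 0.0),
        ([1, 2, 3, 4], [5, 5, 5, 5], 0.0, 5.0),
        ([0, 1, 2, 3], [1, 0, 3, 2], 0.6, 0.6),
    ],
)
def test_regression_worked_examples(a, b, slope, intercept):
    s, i = regression_fit(_plane(a), _plane(b))
    assert s == pytest.approx(slope, abs=1e-12)
    assert i == pytest.approx(intercept, abs=1e-12)


def test_regression_constant_a_is_degenerate():
    with pytest.raises(DegenerateFitError):
        regression_fit(_plane([3, 3, 3, 3]), _plane([1, 2, 3, 4]))


def test_closed_form_equivalence_on_random_images():
    for seed in range(25):
        r = np.random.default_rng(seed)
        a = r.integers(0, 256, (16, 16)).astype(np.uint16)
        b = (0.5 * a + r.integers(0, 64, (16, 16))).astype(np.uint16)
        assert pearson_correlation(a, b) == pytest.approx(_closed_form_pearson(a, b), abs=1e-12)
        s, i = regression_fit(a, b)
        s0, i0 = _closed_form_ols(a, b)
        assert s == pytest.approx(s0, abs=1e-12)
        assert i == pytest.approx(i0, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.25, 8.0),
    offset=st.floats(-50.0, 50.0),
)
def test_pearson_invariant_under_positive_affine_rescaling(seed, scale, offset):
    r = np.random.default_rng(seed)
    a = r.integers(0, 200, (12, 12)).astype(np.float64)
    b = r.integers(0, 200, (12, 12)).astype(np.float64)
    base = pearson_correlation(a, b)
    rescaled = pearson_correlation(a * scale + offset, b)
    assert rescaled == pytest.approx(base, abs=1e-9)


# --- automatic thresholding -------------------------------------------------


def test_auto_threshold_identical_channels_exhausts_to_minimum():
    r = np.random.default_rng(0)
    a = np.sort(r.choice(np.arange(10, 200), size=25, replace=False)).reshape(5, 5)
    th = auto_threshold(a, a)
    assert th.t_a == a.min()
    assert th.t_b == pytest.approx(th.slope * th.t_a + th.intercept)
    rep = coloc_report(a, a, thresholds=th)
    # strict > excludes exactly the single minimum pixel
    assert rep.ncoloc == a.size - 1
    assert rep.rcoloc == 1.0


def _brute_force_threshold(a, b):
    """Independent exhaustive scan over all distinct intensities of A."""
    av, bv = a.ravel().astype(float), b.ravel().astype(float)
    slope, intercept = _closed_form_ols(a, b)
    for t_a in np.unique(av)[::-1]:
        t_b = slope * t_a + intercept
        below = (av <= t_a) | (bv <= t_b)
        if below.sum() < 2:
            continue
        x, y = av[below], bv[below]
        if x.std() == 0 or y.std() == 0:
            return t_a
        if _closed_form_pearson(x, y) <= 0:
            return t_a
    return float(np.min(av))


def test_auto_threshold_matches_brute_force_on_exhaustive_small_cases():
    for seed in range(30):
        r = np.random.default_rng(seed)
        a = r.integers(0, 30, 5).astype(np.uint8).reshape(1, 5)
        b = r.integers(0, 30, 5).astype(np.uint8).reshape(1, 5)
        if np.unique(a).size < 2:
            continue
        th = auto_threshold(a, b)
        assert th.t_a == _brute_force_threshold(a, b)


def test_auto_threshold_criterion_holds_and_fails_one_step_above():
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = r.integers(0, 256, (64, 64)).astype(np.uint8)
        b = r.permutation(a.ravel()).reshape(a.shape)
        th = auto_threshold(a, b)
        av, bv = a.ravel().astype(float), b.ravel().astype(float)
        r_at = below_set_correlation(av, bv, th.t_a, th.t_b)
        assert r_at is None or r_at <= 0
        cands = threshold_candidates(a)
        idx = int(np.where(cands == th.t_a)[0][0])
        if idx > 0:  # not at the extreme: previous candidate must violate
            t_up = cands[idx - 1]
            r_up = below_set_correlation(av, bv, t_up, th.slope * t_up + th.intercept)
            assert r_up is not None and r_up > 0


def test_auto_threshold_degenerate_input():
    with pytest.raises((DegenerateInputError, DegenerateFitError)):
        auto_threshold(np.full((3, 3), 7, np.uint8), np.arange(9, dtype=np.uint8).reshape(3, 3))


# --- report and pixel map ---------------------------------------------------


def test_coloc_report_manual_thresholds_2x2_enumeration():
    a = np.array([[10, 0], [10, 0]], dtype=np.uint8)
    b = np.array([[10, 0], [0, 10]], dtype=np.uint8)
    th = ThresholdPair(t_a=5, t_b=5, slope=float("nan"), intercept=float("nan"))
    rep = coloc_report(a, b, thresholds=th)
    assert rep.quadrant_counts == (1, 1, 1, 1)
    assert rep.ncoloc == 1
    assert rep.pct_volume == 25.0
    assert rep.n_pixels == 4
    assert math.isfinite(rep.slope)
    pix = coloc_pixel_map(a, b, th)
    assert pix[0, 0] and pix.sum() == 1


def test_coloc_report_empty_first_quadrant_flags_rcoloc():
    a = np.array([[1, 2], [3, 4]], dtype=np.uint8)
    b = np.array([[1, 2], [3, 4]], dtype=np.uint8)
    th = ThresholdPair(t_a=10, t_b=10, slope=1.0, intercept=0.0)
    rep = coloc_report(a, b, thresholds=th)
    assert rep.ncoloc == 0
    assert rep.pct_volume == 0.0
    assert rep.rcoloc is None


def test_pixel_map_extremes():
    r = np.random.default_rng(1)
    a = r.integers(1, 200, (16, 16)).astype(np.uint8)
    b = r.integers(1, 200, (16, 16)).astype(np.uint8)
    assert not coloc_pixel_map(a, b, ThresholdPair(255, 255, 1, 0)).any()
    assert coloc_pixel_map(a, b, ThresholdPair(0, 0, 1, 0)).all()


def test_quadrants_partition_and_pixel_map_consistency():
    for seed in range(100):
        r = np.random.default_rng(seed)
        a = r.integers(0, 256, (16, 16)).astype(np.uint8)
        b = r.integers(0, 256, (16, 16)).astype(np.uint8)
        t = ThresholdPair(float(r.integers(0, 255)), float(r.integers(0, 255)), 1.0, 0.0)
        rep = coloc_report(a, b, thresholds=t)
        assert sum(rep.quadrant_counts) == rep.n_pixels == a.size
        assert 0.0 <= rep.pct_volume <= 100.0
        assert coloc_pixel_map(a, b, t).sum() == rep.ncoloc


def test_ncoloc_monotone_in_thresholds():
    r = np.random.default_rng(3)
    a = r.integers(0, 256, (32, 32)).astype(np.uint8)
    b = r.integers(0, 256, (32, 32)).astype(np.uint8)
    counts = [
        coloc_report(a, b, thresholds=ThresholdPair(t, t, 1.0, 0.0)).ncoloc
        for t in range(0, 256, 16)
    ]
    assert all(c0 >= c1 for c0, c1 in zip(counts, counts[1:]))


# --- line profiles ----------------------------------------------------------


def _img_from(plane):
    return MultiChannelImage(channels={"ch": np.asarray(plane, dtype=np.uint8)})


def test_line_profile_constant_and_ramp():
    img = _img_from(np.full((6, 6), 7))
    prof = line_profile(img, (1, 0), (1, 4))
    np.testing.assert_array_equal(prof.intensities["ch"], [7] * 5)

    ramp = np.tile(np.arange(5, dtype=np.uint8), (5, 1))
    prof = line_profile(_img_from(ramp), (2, 0), (2, 4))
    np.testing.assert_array_equal(prof.intensities["ch"], [0, 1, 2, 3, 4])
    np.testing.assert_allclose(prof.distances, [0, 1, 2, 3, 4])


def test_line_profile_diagonal_distances():
    img = _img_from(np.arange(16).reshape(4, 4) % 256)
    prof = line_profile(img, (0, 0), (2, 2))
    np.testing.assert_allclose(prof.distances, [0, math.sqrt(2), 2 * math.sqrt(2)])
    np.testing.assert_array_equal(prof.intensities["ch"], [0, 5, 10])
    assert np.all(np.diff(prof.distances) > 0)


def test_line_profile_preconditions():
    img = _img_from(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        line_profile(img, (0, 0), (0, 0))
    with pytest.raises(ValueError):
        line_profile(img, (0, 0), (9, 9))


# --- gated intensity and fold change ---------------------------------------


def test_cytoplasm_intensity_examples():
    plane = np.full((4, 4), 5, dtype=np.uint8)
    mean, sd, n = cytoplasm_intensity(plane, np.ones((4, 4), bool))
    assert (mean, sd, n) == (5.0, 0.0, 16)

    plane = np.array([[2, 4], [9, 9]], dtype=np.uint8)
    mask = np.array([[True, True], [False, False]])
    assert cytoplasm_intensity(plane, mask)[0] == 3.0

    with pytest.raises(ValueError):
        cytoplasm_intensity(plane, np.zeros((2, 2), bool))


def test_fold_change_examples():
    ratio, lo, hi = fold_change([10, 10], [30, 30], seed=0)
    assert ratio == pytest.approx(3.0)
    ratio, lo, hi = fold_change([4.0, 5.0, 6.0], [4.0, 5.0, 6.0], seed=0)
    assert ratio == pytest.approx(1.0)
    assert lo <= 1.0 <= hi
    with pytest.raises(ValueError):
        fold_change([0.0, 0.0], [1.0], seed=0)
    with pytest.raises(ValueError):
        fold_change([], [1.0], seed=0)
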