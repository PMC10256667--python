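"""Two-channel co-localization statistics.

The quantification follows the standard scatter-plot workflow for a pair of
fluorescence channels A (e.g. a nanocluster probe) and B (e.g. a lipophilic
tracer or an antibody stain):

* ordinary least-squares regression of B on A gives the scatter-plot
  regression line (``slope``, ``intercept``);
* a Costes-style automatic threshold search walks candidate thresholds for A
  downward along that line until the pixel population outside the
  co-localized quadrant (below either threshold) is uncorrelated, yielding
  a linked threshold pair ``(t_a, t_b)``;
* the scatter plot is split into four quadrants at the thresholds;
* ``Rcoloc`` is the Pearson correlation restricted to pixels above both
  thresholds, ``Ncoloc`` the count of such pixels, and ``%Volume`` that
  count as a percentage of all analyzed pixels.

Pixels are gated exclusively by an optional boolean mask (whole image, a
cell, or a cytoplasm region); no intensity-based pixel exclusion is applied
before thresholding.  Undefined correlations (fewer than two pixels, or zero
variance) are reported as ``None``, never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line

from .exceptions import DegenerateFitError, DegenerateInputError
from .imgio import MultiChannelImage

__all__ = [
    "ThresholdPair",
    "ColocalizationReport",
    "LineProfile",
    "pearson_correlation",
    "regression_fit",
    "auto_threshold",
    "threshold_candidates",
    "coloc_report",
    "coloc_pixel_map",
    "line_profile",
    "cytoplasm_intensity",
    "fold_change",
]

#: Maximum number of candidate levels scanned by the automatic threshold
#: search.  Distinct 8-bit images are always scanned exhaustively; richer
#: (16-bit) intensity sets are subsampled evenly to keep the search linear.
MAX_THRESHOLD_CANDIDATES = 512


@dataclass(frozen=True)
class ThresholdPair:
    """Regression-linked intensity thresholds for a channel pair.

    ``t_b`` always equals ``slope * t_a + intercept``; co-localized pixels
    are those *strictly above* both thresholds.
    """

    t_a: float
    t_b: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class ColocalizationReport:
    """The four scatter-plot metrics plus the bookkeeping behind them.

    ``quadrant_counts`` is ordered (A>t & B>t, A>t & B<=t, A<=t & B>t,
    A<=t & B<=t) and always sums to ``n_pixels``.  ``rcoloc`` is ``None``
    when the first quadrant holds fewer than two pixels or has zero variance
    in either channel.
    """

    slope: float
    intercept: float
    pearson_all: float | None
    rcoloc: float | None
    ncoloc: int
    pct_volume: float
    quadrant_counts: tuple[int, int, int, int]
    thresholds: ThresholdPair
    n_pixels: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_all": self.pearson_all,
            "rcoloc": self.rcoloc,
            "ncoloc": self.ncoloc,
            "pct_volume": self.pct_volume,
            "quadrants": list(self.quadrant_counts),
            "t_a": self.thresholds.t_a,
            "t_b": self.thresholds.t_b,
            "n_pixels": self.n_pixels,
        }


@dataclass(frozen=True)
class LineProfile:
    """Per-channel intensities sampled along a straight pixel path."""

    endpoints: tuple[tuple[int, int], tuple[int, int]]
    distances: np.ndarray
    intensities: dict[str, np.ndarray]


def _masked_values(a, b, mask):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if mask is None:
        return a.ravel().astype(np.float64), b.ravel().astype(np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError(f"mask shape {mask.shape} does not match {a.shape}")
    return a[mask].astype(np.float64), b[mask].astype(np.float64)


def _pearson(av: np.ndarray, bv: np.ndarray) -> float | None:
    """Product-moment correlation of two 1-D float arrays.

    Computed as sign(Sab) * sqrt(Sab^2 / (Saa*Sbb)) so that exactly
    proportional inputs return exactly +/-1.0.  Returns None for zero
    variance in either input.
    """
    da = av - av.mean()
    db = bv - bv.mean()
    saa = float(da @ da)
    sbb = float(db @ db)
    if saa == 0.0 or sbb == 0.0:
        return None
    sab = float(da @ db)
    r2 = (sab * sab) / (saa * sbb)
    return math.copysign(math.sqrt(min(r2, 1.0)), sab) if sab != 0.0 else 0.0


def pearson_correlation(a, b, mask=None) -> float | None:
    """Pearson correlation of two intensity planes over ``mask`` pixels.

    Returns ``None`` (undefined) when either channel has zero variance over
    the mask; raises for fewer than two pixels.
    """
    av, bv = _masked_values(a, b, mask)
    if av.size < 2:
        raise ValueError(f"need at least 2 pixels, got {av.size}")
    return _pearson(av, bv)


def regression_fit(a, b, mask=None) -> tuple[float, float]:
    """Ordinary least-squares fit of B on A over ``mask`` pixels."""
    av, bv = _masked_values(a, b, mask)
    if av.size < 2:
        raise ValueError(f"need at least 2 pixels, got {av.size}")
    da = av - av.mean()
    sxx = float(da @ da)
    if sxx == 0.0:
        raise DegenerateFitError("channel A is constant over the mask")
    slope = float(da @ (bv - bv.mean())) / sxx
    intercept = float(bv.mean() - slope * av.mean())
    return slope, intercept


def threshold_candidates(a, mask=None) -> np.ndarray:
    """Descending candidate levels used by :func:`auto_threshold`.

    All distinct intensities of A when there are at most
    ``MAX_THRESHOLD_CANDIDATES`` of them, otherwise an even subsample of the
    sorted distinct values (the extremes are always retained).
    """
    av = np.asarray(a)[np.asarray(mask, bool)] if mask is not None else np.asarray(a).ravel()
    cands = np.unique(av)
    if cands.size > MAX_THRESHOLD_CANDIDATES:
        idx = np.unique(
            np.round(np.linspace(0, cands.size - 1, MAX_THRESHOLD_CANDIDATES)).astype(int)
        )
        cands = cands[idx]
    return cands[::-1].astype(np.float64)


def below_set_correlation(av, bv, t_a, t_b) -> float | None:
    """Pearson correlation of the pixels below either threshold.

    The below-set is the complement of the co-localized quadrant: pixels
    with a <= t_a or b <= t_b.  ``None`` when it holds fewer than two
    pixels or is constant in either channel.
    """
    below = (av <= t_a) | (bv <= t_b)
    if int(below.sum()) < 2:
        return None
    return _pearson(av[below], bv[below])


def auto_threshold(a, b, mask=None) -> ThresholdPair:
    """Costes-style automatic threshold search.

    Candidate thresholds ``t_a`` are walked downward over the (possibly
    subsampled) distinct intensities of A with ``t_b`` tied through the
    regression line.  The below-set at each candidate is the complement of
    the co-localized quadrant (pixels with a <= t_a or b <= t_b); the
    search stops at the first (highest) candidate for which that set is
    non-positively correlated — either Pearson <= 0, or zero variance in
    one channel with at least two below-set pixels.  If no candidate meets
    the criterion the threshold falls to the channel minimum.
    """
    slope, intercept = regression_fit(a, b, mask)
    av, bv = _masked_values(a, b, mask)
    cands = threshold_candidates(a, mask)
    if cands.size < 2:
        raise DegenerateInputError("channel A has fewer than 2 distinct intensities")
    chosen = None
    for t_a in cands:
        r = below_set_correlation(av, bv, t_a, slope * t_a + intercept)
        if r is None or r <= 0.0:
            chosen = t_a
            break
    if chosen is None:
        chosen = cands[-1]
    t_a = float(chosen)
    return ThresholdPair(t_a=t_a, t_b=float(slope * t_a + intercept), slope=slope, intercept=intercept)


def coloc_report(a, b, mask=None, thresholds: ThresholdPair | None = None) -> ColocalizationReport:
    """Full scatter-plot quantification for a channel pair.

    When ``thresholds`` is omitted the automatic search is run first.
    ``rcoloc`` is computed only over first-quadrant pixels (both channels
    above threshold).
    """
    if thresholds is None:
        thresholds = auto_threshold(a, b, mask)
    av, bv = _masked_values(a, b, mask)
    if av.size == 0:
        raise ValueError("mask selects no pixels")
    # reported slope/intercept always describe the data's regression line,
    # even when externally supplied thresholds carry no line of their own
    if math.isfinite(thresholds.slope):
        slope, intercept = thresholds.slope, thresholds.intercept
    else:
        try:
            slope, intercept = regression_fit(a, b, mask)
        except DegenerateFitError:
            slope, intercept = 0.0, float(bv.mean())
    a_hi = av > thresholds.t_a
    b_hi = bv > thresholds.t_b
    q1 = int((a_hi & b_hi).sum())
    q2 = int((a_hi & ~b_hi).sum())
    q3 = int((~a_hi & b_hi).sum())
    q4 = int((~a_hi & ~b_hi).sum())
    n = int(av.size)
    rcoloc = None
    if q1 >= 2:
        rcoloc = _pearson(av[a_hi & b_hi], bv[a_hi & b_hi])
    pearson_all = _pearson(av, bv) if n >= 2 else None
    return ColocalizationReport(
        slope=slope,
        intercept=intercept,
        pearson_all=pearson_all,
        rcoloc=rcoloc,
        ncoloc=q1,
        pct_volume=100.0 * q1 / n,
        quadrant_counts=(q1, q2, q3, q4),
        thresholds=thresholds,
        n_pixels=n,
    )


def coloc_pixel_map(a, b, thresholds: ThresholdPair) -> np.ndarray:
    """Boolean map of pixels above both thresholds (the white overlap map)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    return (a > thresholds.t_a) & (b > thresholds.t_b)


def line_profile(
    img: MultiChannelImage,
    p0: tuple[int, int],
    p1: tuple[int, int],
    channels: list[str] | None = None,
) -> LineProfile:
    """Sample per-channel intensities along the Bresenham path p0 -> p1.

    Distances are Euclidean from ``p0`` to each sampled pixel center, in
    pixel units (no interpolation; the profile reports raw pixel values,
    matching how intensity-vs-distance plots are read off an image).
    """
    p0 = (int(p0[0]), int(p0[1]))
    p1 = (int(p1[0]), int(p1[1]))
    if p0 == p1:
        raise ValueError("line endpoints must differ")
    h, w = img.shape
    for r, c in (p0, p1):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"endpoint ({r}, {c}) outside image of shape {(h, w)}")
    rr, cc = _bresenham_line(p0[0], p0[1], p1[0], p1[1])
    distances = np.hypot(rr - p0[0], cc - p0[1]).astype(np.float64)
    names = channels if channels is not None else img.channel_names
    intensities = {name: img.plane(name)[rr, cc].copy() for name in names}
    return LineProfile(endpoints=(p0, p1), distances=distances, intensities=intensities)


def estimate_background(ch, foreground_mask, margin_px: int = 5) -> float:
    """Mean intensity outside the segmented cells.

    Fluorescence images carry a camera offset plus diffuse background;
    intensity quantification and condition contrasts are computed on
    background-subtracted values.  The estimate is the mean over pixels at
    least ``margin_px`` away from any cell (the margin excludes blur
    halos); the mean, unlike the median, is unbiased under the skewed
    shot-noise distribution of low-count background pixels.
    """
    from scipy import ndimage as _ndi

    ch = np.asarray(ch)
    fg = np.asarray(foreground_mask, dtype=bool)
    if margin_px > 0:
        fg = _ndi.binary_dilation(fg, iterations=margin_px)
    outside = ~fg
    if not outside.any():
        return 0.0
    return float(ch[outside].mean())


def cytoplasm_intensity(ch, cytoplasm) -> tuple[float, float, int]:
    """Mean, sample standard deviation and pixel count over a gated region."""
    ch = np.asarray(ch)
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    if cytoplasm.shape != ch.shape:
        raise ValueError(f"mask shape {cytoplasm.shape} does not match {ch.shape}")
    vals = ch[cytoplasm].astype(np.float64)
    n = int(vals.size)
    if n == 0:
        raise ValueError("cytoplasm mask is empty")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def fold_change(
    means_cond1,
    means_cond2,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Condition-contrast ratio of mean per-cell intensities with bootstrap CI.

    ``ratio = mean(cond2) / mean(cond1)``; the confidence interval comes
    from a seeded percentile bootstrap resampling cells within each
    condition independently.
    """
    m1 = np.asarray(means_cond1, dtype=np.float64)
    m2 = np.asarray(means_cond2, dtype=np.float64)
    if m1.size == 0 or m2.size == 0:
        raise ValueError("both conditions need at least one cell")
    if m1.mean() <= 0:
        raise ValueError("mean of condition 1 must be positive")
    ratio = float(m2.mean() / m1.mean())
    rng = np.random.default_rng(seed)
    i1 = rng.integers(0, m1.size, size=(n_boot, m1.size))
    i2 = rng.integers(0, m2.size, size=(n_boot, m2.size))
    b1 = m1[i1].mean(axis=1)
    b2 = m2[i2].mean(axis=1)
    ok = b1 > 0
    ratios = b2[ok] / b1[ok]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return ratio, float(lo), float(hi)
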