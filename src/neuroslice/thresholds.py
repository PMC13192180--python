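"""Automatic histogram thresholds in the dialects of the FIJI macros.

Three algorithms back the image pipelines:

* ``default dark`` — the classic iterative-intermeans (IsoData variant):
  the threshold is moved to the midpoint of the below- and above-
  threshold means until it stabilizes; "dark" means the background is
  dark, so the foreground is everything *above* the threshold.
* ``minimum dark`` — the histogram is smoothed until bimodal and the
  threshold placed at the valley between the two modes (delegated to
  :func:`skimage.filters.threshold_minimum`).
* ``max entropy`` — Kapur's criterion: the threshold maximizing the sum
  of the Shannon entropies of the background and foreground histogram
  partitions.

The iterative-intermeans and Kapur recurrences are implemented directly
on 256-bin histograms so they can be checked against independent
histogram-recurrence oracles.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_minimum as _sk_threshold_minimum
from skimage.filters import threshold_triangle as _sk_threshold_triangle

__all__ = [
    "isodata_intermeans_bin",
    "kapur_entropy_bin",
    "threshold_default_dark",
    "threshold_minimum_dark",
    "threshold_max_entropy",
    "threshold_triangle_value",
]

_NBINS = 256


def isodata_intermeans_bin(hist: np.ndarray) -> int:
    """Iterative-intermeans threshold bin of a histogram.

    Starting from the histogram midpoint, iterate
    ``t <- round((mean(counts <= t) + mean(counts > t)) / 2)`` until the
    threshold stops moving.  Bins at or below the returned index are
    background.
    """
    hist = np.asarray(hist, dtype=float)
    n = hist.size
    bins = np.arange(n)
    nz = np.nonzero(hist)[0]
    if nz.size <= 1:
        return n // 2  # degenerate histogram: no separable modes
    t = n // 2
    for _ in range(1000):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        if below.sum() == 0:
            mean_b = float(bins[: t + 1].mean())
        else:
            mean_b = float((bins[: t + 1] * below).sum() / below.sum())
        if above.sum() == 0:
            mean_a = float(bins[t + 1 :].mean())
        else:
            mean_a = float((bins[t + 1 :] * above).sum() / above.sum())
        t_new = int(round((mean_b + mean_a) / 2.0))
        if t_new == t:
            return t
        t = t_new
    return t


def kapur_entropy_bin(hist: np.ndarray) -> int:
    """Kapur maximum-entropy threshold bin of a histogram.

    Chooses the bin t maximizing H(background bins <= t) +
    H(foreground bins > t), entropies of the renormalized partitions.
    """
    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum() if hist.sum() > 0 else hist
    c = np.cumsum(p)
    best_t, best_h = 0, -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(p.size - 1):
            w0, w1 = c[t], 1.0 - c[t]
            if w0 <= 0 or w1 <= 0:
                continue
            p0 = p[: t + 1] / w0
            p1 = p[t + 1 :] / w1
            h0 = -np.sum(np.where(p0 > 0, p0 * np.log(p0), 0.0))
            h1 = -np.sum(np.where(p1 > 0, p1 * np.log(p1), 0.0))
            if h0 + h1 > best_h:
                best_h, best_t = h0 + h1, t
    return best_t


def _hist_256(img: np.ndarray):
    """256-bin histogram over the image's own intensity range."""
    img = np.asarray(img)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return None, lo, hi
    hist, edges = np.histogram(img, bins=_NBINS, range=(lo, hi))
    return hist, lo, hi


def _bin_to_value(t: int, lo: float, hi: float) -> float:
    """Upper edge of bin t: pixels strictly above it are foreground."""
    return lo + (t + 1) * (hi - lo) / _NBINS


def threshold_default_dark(img: np.ndarray, invert: bool = False) -> np.ndarray:
    """Binary mask by iterative intermeans, dark-background convention.

    Foreground = pixels above the threshold (or below, when ``invert``
    selects a bright-background convention).  A constant image yields an
    all-background mask with a warning.
    """
    hist, lo, hi = _hist_256(img)
    if hist is None:
        warnings.warn("constant image: default-dark threshold yields empty foreground")
        return np.zeros(np.shape(img), dtype=bool)
    t = isodata_intermeans_bin(hist)
    value = _bin_to_value(t, lo, hi)
    return (img < value) if invert else (img > value)


def threshold_minimum_dark(img: np.ndarray) -> np.ndarray:
    """Binary mask at the valley of a (smoothed-to-)bimodal histogram."""
    img = np.asarray(img)
    if img.min() == img.max():
        warnings.warn("constant image: minimum-dark threshold yields empty foreground")
        return np.zeros(img.shape, dtype=bool)
    try:
        value = _sk_threshold_minimum(img)
    except RuntimeError:  # histogram never becomes bimodal
        warnings.warn("unimodal histogram: falling back to intermeans threshold")
        return threshold_default_dark(img)
    return img > value


def threshold_max_entropy(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Binary mask by Kapur's maximum-entropy criterion.

    When ``mask`` is given the histogram is computed over the masked
    pixels only (and the output is restricted to the mask), so a large
    empty surround does not dominate the partition entropies.
    """
    img = np.asarray(img)
    pixels = img[mask] if mask is not None else img
    hist, lo, hi = _hist_256(pixels)
    if hist is None:
        warnings.warn("constant image: max-entropy threshold yields empty foreground")
        return np.zeros(img.shape, dtype=bool)
    t = kapur_entropy_bin(hist)
    out = img > _bin_to_value(t, lo, hi)
    if mask is not None:
        out &= mask
    return out


def threshold_triangle_value(img: np.ndarray) -> float:
    """Triangle-method threshold value (automatic soma-threshold fallback)."""
    return float(_sk_threshold_triangle(np.asarray(img)))
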