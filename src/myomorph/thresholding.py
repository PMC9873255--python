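"""Fuzzy-entropy (Huang) automatic thresholding.

The threshold ``t`` splits gray levels into background (``g <= t``) and
foreground (``g > t``).  Each pixel's membership to its own class is

    mu(g) = 1 / (1 + |g - mu_class| / C),        C = g_max - g_min,

where ``mu_class`` is the intensity mean of the class the pixel falls in.
The fuzziness of the partition is the Shannon fuzzy entropy

    E(t) = sum_g  h(g) * S(mu(g)),   S(m) = -m ln m - (1 - m) ln(1 - m),

summed over the histogram ``h``.  The Huang threshold is the ``t``
minimizing ``E``; ties are broken toward the lowest ``t``.  A perfectly
crisp partition (every pixel at its class mean) has fuzziness zero.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError

__all__ = ["huang_threshold", "huang_threshold_image", "foreground_threshold"]


def _shannon_fuzzy_entropy(membership: np.ndarray) -> np.ndarray:
    """S(m) elementwise, with the 0*log(0) limit handled. m is in (0.5, 1]."""
    m = np.clip(membership, 1e-15, 1.0)
    c = np.clip(1.0 - membership, 1e-15, 1.0)
    s = -m * np.log(m) - c * np.log(c)
    s[membership >= 1.0] = 0.0
    return s


def huang_threshold(histogram) -> int:
    """Gray-level threshold minimizing the Huang--Wang fuzziness measure.

    Parameters
    ----------
    histogram : array-like of counts
        ``histogram[g]`` is the number of pixels at gray level ``g``.

    Returns
    -------
    int
        Threshold ``t``; pixels with ``g <= t`` are background.

    Raises
    ------
    DegenerateInputError
        If fewer than two gray levels are occupied.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or np.any(hist < 0):
        raise ValueError("histogram must be a 1-D array of nonnegative counts")
    occupied = np.flatnonzero(hist > 0)
    if occupied.size < 2:
        raise DegenerateInputError("histogram occupies fewer than two gray levels")

    g_min, g_max = int(occupied[0]), int(occupied[-1])
    c_norm = float(g_max - g_min)
    levels = np.arange(hist.size, dtype=float)
    cum_w = np.cumsum(hist)
    cum_wg = np.cumsum(hist * levels)
    total_w, total_wg = cum_w[-1], cum_wg[-1]

    # candidates are the occupied levels below g_max: an unoccupied t yields
    # the same partition as the occupied level below it, so the lowest-t
    # tie-break always lands on an occupied level
    best_t, best_e = None, np.inf
    for t in (int(g) for g in occupied[:-1]):
        w0 = cum_w[t]
        w1 = total_w - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = cum_wg[t] / w0
        mu1 = (total_wg - cum_wg[t]) / w1
        lo, hi = levels[: t + 1], levels[t + 1 :]
        m0 = 1.0 / (1.0 + np.abs(lo - mu0) / c_norm)
        m1 = 1.0 / (1.0 + np.abs(hi - mu1) / c_norm)
        e = float(
            hist[: t + 1] @ _shannon_fuzzy_entropy(m0)
            + hist[t + 1 :] @ _shannon_fuzzy_entropy(m1)
        )
        if e < best_e - 1e-15:
            best_e, best_t = e, t
    return int(best_t)


def huang_threshold_image(image: np.ndarray, nbins: int = 256) -> float:
    """Huang threshold of an intensity image, returned in image units.

    The image is binned into ``nbins`` levels spanning its range; the
    returned value ``v`` is such that foreground pixels satisfy
    ``image > v``.

    Raises
    ------
    DegenerateInputError
        If the image is constant.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if not hi > lo:
        raise DegenerateInputError("constant image has no threshold")
    edges = np.linspace(lo, hi, nbins + 1)
    idx = np.clip(np.digitize(img.ravel(), edges) - 1, 0, nbins - 1)
    hist = np.bincount(idx, minlength=nbins)
    t = huang_threshold(hist)
    return float(edges[t + 1])


def foreground_threshold(
    image: np.ndarray, nbins: int = 256, min_contrast: float = 0.25
) -> float | None:
    """Huang threshold with a bimodality guard.

    Returns the threshold in image units, or ``None`` when the image has
    no credible foreground: a constant image, or a split whose class
    means are separated by less than ``min_contrast`` of the image range
    (the signature of thresholding a unimodal noise distribution down
    the middle).
    """
    img = np.asarray(image, dtype=float)
    try:
        thr = huang_threshold_image(img, nbins)
    except DegenerateInputError:
        return None
    fg = img > thr
    if not fg.any() or fg.all():
        return None
    contrast = (img[fg].mean() - img[~fg].mean()) / (img.max() - img.min())
    if contrast < min_contrast:
        return None
    return thr
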