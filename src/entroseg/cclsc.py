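"""Color-Component-Level Spatial Correlation (CCLSC) entropy thresholding.

The threshold for one color component is chosen by maximizing the sum of
weighted Shannon entropies of the "object" (intensity <= t) and "background"
(intensity > t) partitions of a 2-D histogram that couples each pixel's
intensity with the spatial homogeneity of its neighbourhood.

For a component image ``f`` of size P x Q the similarity index of the pixel
at (x, y) is

    g(x, y) = #{(i, j) in the N x N neighbourhood : |f(i,j) - f(x,y)| <= eps}

which is at least 1 (the center always matches itself) and at most N^2.
Homogeneous object/background interiors give large g; edges give mid-range
g.  The normalized CCLSC histogram is the product of the two marginal
distributions,

    h_hat(k, m) = [#pixels with f = k / (P Q)] * [#pixels with g = m / (P Q)],

for intensity k in {0..255} and similarity index m in {1..N^2}.  With
P_O(t) = sum_{k<=t} sum_m h_hat and P_B(t) = 1 - P_O(t), the two region
entropies are

    H_O(t) = - sum_{k<=t} sum_m (h_hat/P_O) ln(h_hat/P_O) * w(m, N)
    H_B(t) = - sum_{k>t}  sum_m (h_hat/P_B) ln(h_hat/P_B) * w(m, N)

with the Gaussian weight  w(m, N) = 5 exp(-(m - N^2/2)^2 / 32)  emphasizing
the mid-range (edge-like) similarity indices, and the selected threshold is

    T = argmax_t [ H_O(t) + H_B(t) ]

over all t in {0..254} with P_O(t) > 0 and P_B(t) > 0, smallest t on ties.
The 0 ln 0 := 0 convention applies to empty histogram cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._validation import require_channel, require_same_shape
from .errors import DegenerateImageError


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the CCLSC threshold selection.

    Attributes
    ----------
    n : int
        Neighbourhood side N, odd, default 5.  Small N suits low
        magnification; larger N suits higher magnification.
    epsilon : int
        Intensity tolerance eps of the similarity comparison (inclusive),
        default 5.
    joint_histogram : bool
        If True, use the true joint distribution of (intensity, similarity
        index) instead of the product of the marginals.  The product form is
        the default and the operative definition.
    exclude_masked : bool
        If True, pixels of intensity 0 (those zeroed by background removal)
        are dropped from both marginals.  Default False: every pixel of the
        P x Q raster contributes.
    """

    n: int = 5
    epsilon: int = 5
    joint_histogram: bool = False
    exclude_masked: bool = False

    def __post_init__(self):
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError(f"N must be an odd integer >= 3, got {self.n}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")


@dataclass
class CCLSCHistogram:
    """Normalized CCLSC histogram of one channel.

    ``table[k, m-1]`` holds h_hat(k, m) for k in 0..255, m in 1..N^2;
    ``pixel_hist`` and ``sim_hist`` are the raw intensity / similarity-index
    counts the table was built from.
    """

    table: np.ndarray
    pixel_hist: np.ndarray
    sim_hist: np.ndarray
    n: int


@dataclass
class ThresholdResult:
    """Selected threshold plus the diagnostic entropy curves.

    ``phi_curve[t]``, ``h_object_curve[t]`` and ``h_background_curve[t]``
    cover t = 0..254; inadmissible t (one region empty) hold NaN.
    """

    threshold: int
    phi_curve: np.ndarray
    h_object_curve: np.ndarray
    h_background_curve: np.ndarray
    histogram: CCLSCHistogram = field(repr=False, default=None)


def similarity_map(ch: np.ndarray, cfg: EntropyConfig | None = None) -> np.ndarray:
    """Similarity index g(x, y) of every pixel (replicate-padded borders).

    Raises
    ------
    DegenerateImageError
        If the image is smaller than the N x N neighbourhood.
    """
    cfg = cfg or EntropyConfig()
    ch = require_channel(ch)
    n = cfg.n
    if ch.shape[0] < n or ch.shape[1] < n:
        raise DegenerateImageError(
            f"image {ch.shape} smaller than the {n}x{n} neighbourhood"
        )
    r = n // 2
    padded = np.pad(ch.astype(np.int16), r, mode="edge")
    center = ch.astype(np.int16)
    h, w = ch.shape
    g = np.zeros((h, w), dtype=np.int32)
    for di in range(n):
        for dj in range(n):
            window = padded[di : di + h, dj : dj + w]
            g += np.abs(window - center) <= cfg.epsilon
    return g


def cclsc_histogram(
    ch: np.ndarray, sim: np.ndarray, cfg: EntropyConfig | None = None
) -> CCLSCHistogram:
    """Build the normalized CCLSC histogram from a channel and its g map."""
    cfg = cfg or EntropyConfig()
    ch = require_channel(ch)
    require_same_shape(ch, sim)
    m_levels = cfg.n * cfg.n
    flat_f = np.asarray(ch).ravel()
    flat_g = np.asarray(sim).ravel()
    if cfg.exclude_masked:
        keep = flat_f > 0
        flat_f = flat_f[keep]
        flat_g = flat_g[keep]
        if flat_f.size == 0:
            raise DegenerateImageError("all pixels are masked out")
    total = flat_f.size
    pixel_hist = np.bincount(flat_f, minlength=256)
    sim_hist = np.bincount(flat_g - 1, minlength=m_levels)
    if cfg.joint_histogram:
        table = np.zeros((256, m_levels), dtype=np.float64)
        np.add.at(table, (flat_f, flat_g - 1), 1.0)
        table /= total
    else:
        table = np.outer(pixel_hist / total, sim_hist / total)
    return CCLSCHistogram(
        table=table, pixel_hist=pixel_hist, sim_hist=sim_hist, n=cfg.n
    )


def region_probabilities(hist: CCLSCHistogram, t: int):
    """Cumulative object/background probabilities (P_O(t), P_B(t))."""
    if not (0 <= t <= 255):
        raise ValueError(f"threshold t must be in [0, 255], got {t}")
    p_o = float(hist.table[: t + 1].sum())
    p_b = float(hist.table[t + 1 :].sum())
    return p_o, p_b


def weight(m, n: int):
    """Entropy weight  5 exp(-(m - N^2/2)^2 / 32), maximal (=5) at m = N^2/2."""
    m = np.asarray(m, dtype=np.float64)
    out = 5.0 * np.exp(-((m - (n * n) / 2.0) ** 2) / 32.0)
    return float(out) if out.ndim == 0 else out


def region_entropy(
    hist: CCLSCHistogram, t: int, region: str, cfg: EntropyConfig | None = None
) -> float:
    """Weighted Shannon entropy of the object (k <= t) or background (k > t)
    restriction of the CCLSC distribution.

    Raises
    ------
    DegenerateImageError
        If the requested region has zero probability mass.
    """
    if region not in ("object", "background"):
        raise ValueError("region must be 'object' or 'background'")
    sub = hist.table[: t + 1] if region == "object" else hist.table[t + 1 :]
    p = sub.sum()
    if p <= 0.0:
        raise DegenerateImageError(f"{region} probability is zero at t={t}")
    w = weight(np.arange(1, hist.n * hist.n + 1), hist.n)
    q = sub / p
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)
    return float(-(terms * w[None, :]).sum())


def find_threshold(ch: np.ndarray, cfg: EntropyConfig | None = None) -> ThresholdResult:
    """Entropy-optimal threshold of one channel by exhaustive scan.

    Scans every t in {0..254} with both region probabilities positive,
    computes Phi(t) = H_O(t) + H_B(t), and returns the smallest maximizer
    together with the full curves.

    Raises
    ------
    DegenerateImageError
        If the channel holds fewer than two distinct intensity values (no
        admissible t exists).
    """
    cfg = cfg or EntropyConfig()
    ch = require_channel(ch)
    sim = similarity_map(ch, cfg)
    hist = cclsc_histogram(ch, sim, cfg)
    if np.count_nonzero(hist.pixel_hist) < 2:
        raise DegenerateImageError(
            "channel holds a single intensity value; no threshold exists"
        )
    table = hist.table
    w = weight(np.arange(1, cfg.n * cfg.n + 1), cfg.n)
    with np.errstate(divide="ignore"):
        logt = np.where(table > 0, np.log(np.where(table > 0, table, 1.0)), 0.0)
    # Per-intensity cumulants: H over a region reduces to
    #   H = -(sum h ln h w - ln P * sum h w) / P
    # so cumulative sums over k give every t in one pass.
    a = (table * logt * w[None, :]).sum(axis=1)
    b = (table * w[None, :]).sum(axis=1)
    p = table.sum(axis=1)
    cum_a, cum_b, cum_p = np.cumsum(a), np.cumsum(b), np.cumsum(p)
    tot_a, tot_b = cum_a[-1], cum_b[-1]
    counts = np.cumsum(hist.pixel_hist)

    h_o = np.full(255, np.nan)
    h_b = np.full(255, np.nan)
    for t in range(255):
        if counts[t] == 0 or counts[t] == counts[-1]:
            continue
        p_o = cum_p[t]
        p_b = cum_p[-1] - cum_p[t]
        h_o[t] = -(cum_a[t] - math.log(p_o) * cum_b[t]) / p_o
        h_b[t] = -((tot_a - cum_a[t]) - math.log(p_b) * (tot_b - cum_b[t])) / p_b
    phi = h_o + h_b
    threshold = int(np.nanargmax(phi))  # nanargmax returns the first maximizer
    return ThresholdResult(
        threshold=threshold,
        phi_curve=phi,
        h_object_curve=h_o,
        h_background_curve=h_b,
        histogram=hist,
    )
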