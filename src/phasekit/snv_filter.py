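"""Automatic quality-threshold estimation for small-variant callsets.

Long-read SNV/indel callers often emit a QUAL distribution with two
bell-shaped components: a low-quality mode dominated by errors and a
high-quality mode of real variants. The filter locates the valley
between the two modes on a smoothed histogram and uses it as the
callset-wide QUAL cutoff, so no manual threshold has to be picked per
sample or per technology.

Estimator
---------
1. Histogram the QUAL values over [min, max] (``bins`` bins).
2. Smooth with a centered moving average of width ``smooth_window``.
3. Find local maxima (``scipy.signal.find_peaks``, minimum peak
   distance = the smoothing window so one mode yields one peak).
4. If at least two peaks exist, take the two with the highest smoothed
   density (ties broken toward the most separated pair) and locate the
   minimum-density bin strictly between them.
5. Refine the valley position by a quadratic fit to the smoothed
   density around that bin: the bin grid quantizes the estimate and
   the valley is locally parabolic, so the vertex of the fit is a
   better estimate of the density minimum than the bin midpoint.
6. Guard against spurious bimodality: the valley must be below 90% of
   the lower mode's density, otherwise the distribution is declared
   unimodal and no threshold is set.

Fewer than 100 QUAL values are never called bimodal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

#: below this many sites the histogram is too noisy to trust a valley
MIN_SITES = 100

#: the valley must be at most this fraction of the lower mode's density
VALLEY_DEPTH_RATIO = 0.9

LOWQUAL_FILTER = "phasekit_lowqual"


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the bimodal threshold search."""

    threshold: float | None
    mode_lo: float | None
    mode_hi: float | None
    n_sites: int
    method: str = "smoothed-histogram-valley"
    bimodal: bool = False

    def __post_init__(self) -> None:
        if self.bimodal:
            if self.threshold is None or self.mode_lo is None or self.mode_hi is None:
                raise ValueError("bimodal result requires threshold and both modes")
            if not self.mode_lo < self.threshold < self.mode_hi:
                raise ValueError("threshold must lie strictly between the modes")
        elif self.threshold is not None:
            raise ValueError("non-bimodal result cannot carry a threshold")


def _unimodal(n: int) -> ThresholdResult:
    return ThresholdResult(threshold=None, mode_lo=None, mode_hi=None, n_sites=n)


def estimate_quality_threshold(
    quals: Sequence[float],
    bins: int = 200,
    smooth_window: int = 9,
) -> ThresholdResult:
    """Locate the QUAL threshold between the two modes of a callset.

    Parameters
    ----------
    quals
        Non-negative QUAL values (one per call).
    bins
        Histogram resolution over [min, max].
    smooth_window
        Width (odd, in bins) of the centered moving average.

    Returns
    -------
    ThresholdResult
        ``bimodal=False`` (threshold ``None``) when fewer than 100
        values are given, fewer than two modes are found, or the
        valley is not deep enough.
    """
    if bins < 1:
        raise ValueError("bins must be positive")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd positive integer")
    q = np.asarray(quals, dtype=float)
    if q.size and q.min() < 0:
        raise ValueError("negative QUAL values are not allowed")
    if q.size < MIN_SITES:
        return _unimodal(q.size)
    lo, hi = float(q.min()), float(q.max())
    if hi <= lo:
        return _unimodal(q.size)

    counts, edges = np.histogram(q, bins=bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")

    peaks, _ = find_peaks(smoothed, distance=smooth_window)
    if peaks.size < 2:
        return _unimodal(q.size)

    i, j = _pick_two_modes(peaks, smoothed)
    inner = smoothed[i + 1 : j]
    if inner.size == 0:
        return _unimodal(q.size)
    v = i + 1 + int(np.argmin(inner))
    if smoothed[v] >= VALLEY_DEPTH_RATIO * min(smoothed[i], smoothed[j]):
        return _unimodal(q.size)

    threshold = _refine_valley(centers, smoothed, v, i, j, smooth_window)
    return ThresholdResult(
        threshold=float(threshold),
        mode_lo=float(centers[i]),
        mode_hi=float(centers[j]),
        n_sites=int(q.size),
        bimodal=True,
    )


def _pick_two_modes(peaks: np.ndarray, smoothed: np.ndarray) -> tuple[int, int]:
    """The two highest peaks; density ties broken toward separation."""
    heights = smoothed[peaks]
    order = np.argsort(heights, kind="stable")
    top = heights[order[-2]]
    tied = peaks[heights >= top]
    if tied.size > 2:
        return int(tied.min()), int(tied.max())
    i, j = sorted(int(p) for p in peaks[order[-2:]])
    return i, j


def _refine_valley(
    centers: np.ndarray, smoothed: np.ndarray, v: int, i: int, j: int, window: int
) -> float:
    lo = max(i + 1, v - window)
    hi = min(j, v + window + 1)
    x, y = centers[lo:hi], smoothed[lo:hi]
    if x.size >= 3:
        c2, c1, _ = np.polyfit(x, y, 2)
        if c2 > 0:
            vertex = -c1 / (2.0 * c2)
            if x[0] <= vertex <= x[-1]:
                return vertex
    return float(centers[v])


def apply_quality_filter(
    records: Sequence[VariantRecord],
    result: ThresholdResult,
    mode: str = "soft",
) -> list[VariantRecord]:
    """Filter a callset at the estimated threshold.

    ``soft`` tags failing records with FILTER ``phasekit_lowqual`` and
    passing records with PASS; ``hard`` drops failing records. Records
    pass when ``qual >= threshold`` (ties are kept). A non-bimodal
    result leaves the callset untouched.
    """
    if mode not in ("soft", "hard"):
        raise ValueError(f"mode must be 'soft' or 'hard', got {mode!r}")
    if not result.bimodal:
        warnings.warn("QUAL distribution not bimodal; no filtering applied")
        return list(records)
    threshold = result.threshold
    assert threshold is not None

    out: list[VariantRecord] = []
    n_missing = 0
    for rec in records:
        if rec.qual is None:
            n_missing += 1
            passes = False
        else:
            passes = rec.qual >= threshold
        if passes:
            out.append(rec.replace(filter=frozenset({"PASS"})))
        elif mode == "soft":
            out.append(rec.replace(filter=frozenset({LOWQUAL_FILTER})))
    if n_missing:
        logger.warning("%d records without QUAL treated as below threshold", n_missing)
    return out
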