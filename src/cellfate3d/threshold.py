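"""Automatic foreground/background separation for one channel's z-stack.

One threshold is estimated per (position, channel) stack — never per slice —
from a histogram pooled over the central block of z-slices, using Yen's
maximum-correlation criterion.  Out-of-focus halos concentrate in the extreme
slices of the stack, so restricting estimation to the center keeps the
threshold anchored to in-focus nuclei; the single threshold is then applied
to every slice.  A stack whose threshold is less than ``signal_fold``
(default 10) times its background mean is declared devoid of biological
signal and contributes an empty mask.

Yen's criterion for a cut t over normalized bin probabilities p_i with
cumulative P(t) is

    TC(t) = -ln[ (sum_{i<=t} p_i^2)(sum_{i>t} p_i^2) / (P(t)^2 (1-P(t))^2) ]

and the threshold is the bin edge maximizing TC, ties broken toward the
lower cut.  It favors low-complexity foreground masks, which suits uniformly
stained nuclei.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import NoContrastError

__all__ = [
    "Histogram", "ThresholdDecision", "histogram_from_planes", "yen_threshold",
    "estimate_stack_threshold", "apply_signal_rule", "segment_foreground",
    "robust_background_threshold", "DEFAULT_SIGNAL_FOLD", "DEFAULT_CENTRAL_FRACTION",
]

log = logging.getLogger(__name__)

DEFAULT_SIGNAL_FOLD = 10.0
DEFAULT_CENTRAL_FRACTION = 0.2
DEFAULT_N_BINS = 256
_TINY = 1e-12


@dataclass
class Histogram:
    """Binned pixel intensities: ``counts[i]`` pixels in ``[edges[i], edges[i+1])``."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise ValueError("counts and bin_edges must be 1-D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if (self.counts < 0).any():
            raise ValueError("negative bin count")
        if not (np.diff(self.bin_edges) > 0).all():
            raise ValueError("bin edges must be strictly ascending")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass
class ThresholdDecision:
    """Outcome of threshold estimation for one stack.

    ``has_signal`` False (threshold +inf) means every slice of the stack gets
    an all-background mask for this channel.
    """

    threshold: float
    has_signal: bool
    background_mean: float
    fold_over_background: float
    central_slices_used: list[int] = field(default_factory=list)
    method: str = "yen"


def histogram_from_planes(
    planes: Iterable[np.ndarray], n_bins: int = DEFAULT_N_BINS
) -> Histogram:
    """Pool pixels from one or more planes into ``n_bins`` equal-width bins
    spanning [0, max observed]."""
    pixels = np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in planes])
    if pixels.size == 0:
        raise ValueError("no pixels")
    top = float(pixels.max())
    if top <= 0:
        raise NoContrastError("no contrast: all pixels are zero")
    counts, edges = np.histogram(pixels, bins=n_bins, range=(0.0, top))
    return Histogram(counts=counts, bin_edges=edges)


def _yen_tc(hist: Histogram) -> np.ndarray:
    """TC(t) for every interior cut (after bin i, i = 0..n-2); -inf where undefined."""
    total = hist.n_pixels
    p = hist.counts / total
    P1 = np.cumsum(p)[:-1]
    S1 = np.cumsum(p * p)[:-1]
    S_total = float(np.sum(p * p))
    P2 = 1.0 - P1
    S2 = S_total - S1
    tc = np.full(len(p) - 1, -np.inf)
    valid = (P1 > 0) & (P2 > 0) & (S1 > 0) & (S2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tc[valid] = (
            2 * np.log(P1[valid]) + 2 * np.log(P2[valid])
            - np.log(S1[valid]) - np.log(S2[valid])
        )
    return tc


def yen_threshold(hist: Histogram) -> float:
    """Threshold (a bin edge) maximizing Yen's criterion; ties go to the lower cut.

    Raises
    ------
    NoContrastError
        If fewer than two bins are occupied.
    """
    if int(np.count_nonzero(hist.counts)) < 2:
        raise NoContrastError("no contrast: fewer than two occupied bins")
    tc = _yen_tc(hist)
    i = int(np.argmax(tc))  # first occurrence == lower threshold on ties
    if not np.isfinite(tc[i]):
        raise NoContrastError("no contrast: criterion undefined at every cut")
    return float(hist.bin_edges[i + 1])


def apply_signal_rule(
    threshold: float, background_mean: float, signal_fold: float = DEFAULT_SIGNAL_FOLD
) -> bool:
    """True when the threshold is at least ``signal_fold`` times the background mean.

    A False result marks the stack as devoid of meaningful biological signal:
    it contributes zero foreground area for the channel.  Exactly
    ``signal_fold``-fold passes ("less than ten-fold" fails).
    """
    if background_mean < 0:
        raise ValueError("background_mean must be >= 0")
    return threshold >= signal_fold * background_mean


def central_slice_indices(n_slices: int, central_fraction: float) -> list[int]:
    """Indices of the centered block of ceil(central_fraction * n) slices (min 1)."""
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must be in (0, 1]")
    n_central = max(1, math.ceil(central_fraction * n_slices))
    start = (n_slices - n_central) // 2
    return list(range(start, start + n_central))


def estimate_stack_threshold(
    planes: np.ndarray | Sequence[np.ndarray],
    central_fraction: float = DEFAULT_CENTRAL_FRACTION,
    n_bins: int = DEFAULT_N_BINS,
    signal_fold: float = DEFAULT_SIGNAL_FOLD,
    method: str = "yen",
) -> ThresholdDecision:
    """Estimate one threshold for a whole (corrected) stack from its central slices.

    Pools the histogram of the centered block of ``ceil(central_fraction *
    n_slices)`` slices, thresholds it with ``method`` ("yen" or
    "robust_background"), takes the background mean as the mean of pooled
    pixels strictly below the threshold, and applies the signal-absence rule.
    A histogram without contrast yields ``has_signal=False`` with threshold
    +inf (empty masks), logged rather than raised.
    """
    planes = np.asarray(planes, dtype=np.float64)
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    central = central_slice_indices(planes.shape[0], central_fraction)
    pooled = planes[central]
    try:
        hist = histogram_from_planes(pooled, n_bins=n_bins)
        if method == "yen":
            t = yen_threshold(hist)
        elif method == "robust_background":
            t = robust_background_threshold(hist)
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    except NoContrastError as e:
        log.info("stack has no contrast (%s); declaring absence of signal", e)
        return ThresholdDecision(
            threshold=math.inf, has_signal=False, background_mean=float(pooled.mean()),
            fold_over_background=0.0, central_slices_used=central, method=method,
        )
    below = pooled[pooled < t]
    background_mean = float(below.mean()) if below.size else 0.0
    fold = t / max(background_mean, _TINY)
    return ThresholdDecision(
        threshold=t,
        has_signal=apply_signal_rule(t, background_mean, signal_fold),
        background_mean=background_mean,
        fold_over_background=fold,
        central_slices_used=central,
        method=method,
    )


def segment_foreground(plane: np.ndarray, decision: ThresholdDecision) -> np.ndarray:
    """Binary foreground mask: ``plane > threshold``, or all-False without signal."""
    plane = np.asarray(plane)
    if not decision.has_signal:
        return np.zeros(plane.shape, dtype=bool)
    return plane > decision.threshold


def robust_background_threshold(
    hist: Histogram, trim_fraction: float = 0.05, k_sd: float = 2.0
) -> float:
    """Alternative backend: trimmed mean + ``k_sd`` trimmed SDs.

    Discards the top and bottom ``trim_fraction`` of pixel mass (fractional
    bins pro-rated), then returns mean + k_sd * SD of the remaining mass,
    with intensities taken at bin centers.  Zero remaining SD degenerates to
    the trimmed mean (logged).
    """
    n = hist.n_pixels
    if n < 10:
        raise ValueError(f"need >= 10 pixels, got {n}")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = trim_fraction * n
    weights = hist.counts.astype(np.float64)
    # trim k pixels of mass from each tail, pro-rating partial bins
    for idx in (np.arange(len(weights)), np.arange(len(weights))[::-1]):
        remaining = k
        for i in idx:
            if remaining <= 0:
                break
            take = min(weights[i], remaining)
            weights[i] -= take
            remaining -= take
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    w_total = weights.sum()
    if w_total <= 0:
        raise ValueError("trimming removed all pixels")
    mean = float(np.average(centers, weights=weights))
    var = float(np.average((centers - mean) ** 2, weights=weights))
    if var <= 0:
        log.info("robust background: zero trimmed SD; returning trimmed mean")
        return mean
    return mean + k_sd * math.sqrt(var)
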