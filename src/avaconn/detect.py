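"""Avalanche detection and branching-parameter estimation.

The chain is: z-score each region's series over the full recording,
binarize at |z| > threshold (default 3), OR-pool samples into time bins,
extract maximal contiguous runs of bins with any activity (the avalanches),
and estimate the branching parameter sigma as the geometric mean, over
avalanches, of each avalanche's geometric-mean descendant/ancestor event
ratio.  A branching parameter near 1 indicates critical dynamics; the time
bin is selected as the candidate whose sigma is closest to 1.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateSignalError, ParameterError, UndefinedEstimateError
from .types import Avalanche, BinarizedRaster, BranchingEstimate, ZScoredSeries

__all__ = [
    "zscore_series",
    "binarize",
    "bin_raster",
    "detect_avalanches",
    "branching_parameter",
    "select_bin_size",
]

logger = logging.getLogger(__name__)

#: Default activation threshold in z-units.
DEFAULT_THRESHOLD = 3.0
#: Default minimum avalanche duration in bins.
DEFAULT_MIN_DURATION = 10
#: Candidate bin sizes examined by default (larger bins allowed with a warning).
DEFAULT_CANDIDATE_BINS = (1, 2, 3, 4, 5)


def zscore_series(ts: np.ndarray, fs: float, region_labels=None) -> ZScoredSeries:
    """Standardize each region's series to mean 0 and unit population SD.

    Parameters
    ----------
    ts:
        Regions x samples real matrix.
    fs:
        Sampling rate in Hz (carried through for later binning).

    Raises
    ------
    DegenerateSignalError
        If any region is constant (zero standard deviation).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ParameterError("time series must be a regions x samples matrix")
    if ts.shape[1] < 2:
        raise ParameterError("need at least 2 samples per region")
    mean = ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1, keepdims=True)  # population (1/N) convention
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        labels = region_labels or [str(i) for i in range(ts.shape[0])]
        names = ", ".join(str(labels[i]) for i in flat[:5])
        raise DegenerateSignalError(
            f"constant region(s) cannot be z-scored: {names}"
        )
    return ZScoredSeries(values=(ts - mean) / sd, fs=fs, region_labels=region_labels)


def binarize(z: ZScoredSeries, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Mark suprathreshold samples: True iff |z| > threshold (strict).

    Both positive and negative excursions count.  Returns a regions x
    samples boolean matrix at sample resolution.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    return np.abs(z.values) > threshold


def bin_raster(
    point_raster: np.ndarray,
    bin_size: int,
    fs: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> BinarizedRaster:
    """OR-pool a sample-resolution boolean matrix into time bins.

    A region is active in a bin iff it is active at >= 1 sample inside the
    bin; a trailing partial bin is dropped.  Bin sizes above 5 samples are
    allowed but warned about (at the native rate they start to blur the
    fast dynamics the analysis targets).
    """
    if bin_size < 1:
        raise ParameterError("bin_size must be >= 1")
    if bin_size > max(DEFAULT_CANDIDATE_BINS):
        warnings.warn(
            f"bin_size={bin_size} is above the usual 1-5 sample range",
            stacklevel=2,
        )
    pr = np.asarray(point_raster, dtype=bool)
    n_regions, n_samples = pr.shape
    n_bins = n_samples // bin_size
    pooled = (
        pr[:, : n_bins * bin_size].reshape(n_regions, n_bins, bin_size).any(axis=2)
    )
    return BinarizedRaster(active=pooled, bin_size=bin_size, fs=fs, threshold=threshold)


def detect_avalanches(
    raster: BinarizedRaster, min_duration: int = DEFAULT_MIN_DURATION
) -> list[Avalanche]:
    """Extract avalanches: maximal runs of bins with >= 1 active region.

    An avalanche begins when any region is active after a quiescent bin and
    ends when all regions fall silent.  Runs touching the recording edges
    are kept.  Avalanches shorter than ``min_duration`` bins are discarded
    (default 10; pass 1 to keep all).
    """
    if min_duration < 1:
        raise ParameterError("min_duration must be >= 1")
    active = raster.active
    any_active = active.any(axis=0).astype(np.int8)
    edges = np.diff(np.concatenate(([0], any_active, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    avalanches = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_duration:
            continue
        sl = active[:, s : e + 1].copy()
        avalanches.append(Avalanche(raster=sl, start_bin=int(s), end_bin=int(e)))
    return avalanches


def branching_parameter(avalanches: Iterable[Avalanche]) -> BranchingEstimate:
    """Estimate the branching parameter from a set of avalanches.

    For avalanche i with per-bin event counts n(1)..n(N):

        sigma_i = [ prod_{j=1}^{N-1} n(j+1) / n(j) ] ^ (1 / (N-1))

    and the dataset estimate is the geometric mean of the sigma_i.
    Avalanches of duration 1 have no descendant bin and are excluded.

    Raises
    ------
    UndefinedEstimateError
        If no avalanche has duration >= 2.
    """
    log_sigmas = []
    for av in avalanches:
        if av.duration < 2:
            continue
        n = av.events_per_bin.astype(float)
        log_sigmas.append(np.mean(np.diff(np.log(n))))
    if not log_sigmas:
        raise UndefinedEstimateError(
            "branching parameter undefined: no avalanche of duration >= 2"
        )
    log_sigmas = np.asarray(log_sigmas)
    return BranchingEstimate(
        sigma_per_avalanche=np.exp(log_sigmas),
        sigma=float(np.exp(log_sigmas.mean())),
        n_avalanches=log_sigmas.size,
    )


def select_bin_size(
    point_raster: np.ndarray,
    candidate_bins: Sequence[int] = DEFAULT_CANDIDATE_BINS,
    min_duration: int = DEFAULT_MIN_DURATION,
    fs: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[int, dict[int, float]]:
    """Pick the time bin whose branching parameter is closest to 1.

    Computes sigma at every candidate bin size and returns the winning bin
    plus the full sigma-per-candidate map.  Ties break toward the smaller
    bin; candidates with no valid avalanche are skipped with a warning.
    """
    candidates = sorted(set(int(b) for b in candidate_bins))
    if not candidates:
        raise ParameterError("candidate_bins must be nonempty")
    sigmas: dict[int, float] = {}
    for b in candidates:
        binned = bin_raster(point_raster, b, fs=fs, threshold=threshold)
        avs = detect_avalanches(binned, min_duration=min_duration)
        try:
            sigmas[b] = branching_parameter(avs).sigma
        except UndefinedEstimateError:
            logger.warning("bin size %d skipped: no valid avalanches", b)
    if not sigmas:
        raise UndefinedEstimateError("no candidate bin size yields any avalanche")
    best = min(sigmas, key=lambda b: (abs(sigmas[b] - 1.0), b))
    return best, sigmas
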