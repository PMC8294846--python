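"""Transition matrices: per-avalanche estimation, aggregation, variants.

The avalanche-level transition matrix (TM) entry (i, j) is the conditional
frequency with which region j is active one time bin after region i, within
one avalanche.  TMs are averaged entrywise over avalanches to participant
level, over participants to group level, and finally symmetrized.  Entries
whose denominator is zero (region i never an ancestor) are undefined (NaN)
and excluded from averages by default.

Two variants of the main analysis are provided: a binary long-delay TM that
links avalanche starters to every region recruited later (robust to any
zero-lag mixing), and a frequency-band path that band-pass filters the
continuous series before the standard chain.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError, UndefinedEstimateError
from .types import Avalanche, BandSpec, BANDS, TransitionMatrix

__all__ = [
    "avalanche_tm",
    "aggregate_tms",
    "symmetrize",
    "long_delay_tm",
    "bandpass",
    "tm_counts",
]


def tm_counts(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transition and ancestor counts of one avalanche raster.

    Returns ``(numerator, denominator)`` where ``numerator[i, j]`` counts
    bins t among the first duration-1 bins with i active at t and j active
    at t+1, and ``denominator[i]`` counts bins t in that range with i
    active.
    """
    r = np.asarray(raster, dtype=bool)
    a = r[:, :-1].astype(np.float64)
    numerator = a @ r[:, 1:].astype(np.float64).T
    denominator = a.sum(axis=1)
    return numerator, denominator


def avalanche_tm(av: Avalanche) -> TransitionMatrix:
    """Estimate the lag-one transition matrix of a single avalanche.

    probs(i, j) = (# bins with i active at t and j active at t+1)
                / (# bins with i active at t),  t over the first
    duration-1 bins; rows of regions never active in that range are
    undefined (NaN).  The diagonal follows the same rule.
    """
    if av.duration < 2:
        raise UndefinedEstimateError("TM undefined for avalanches of duration < 2")
    num, den = tm_counts(av.raster)
    n = av.raster.shape[0]
    probs = np.full((n, n), np.nan)
    rows = den > 0
    probs[rows] = num[rows] / den[rows, None]
    ancestor_counts = np.repeat(den.astype(np.int64)[:, None], n, axis=1)
    return TransitionMatrix(
        probs=probs, level="avalanche", ancestor_counts=ancestor_counts
    )


def aggregate_tms(
    tms: list[TransitionMatrix], level: str, undefined_as_zero: bool = False
) -> TransitionMatrix:
    """Entrywise mean of TMs, ignoring undefined entries.

    An output entry is defined iff it is defined in at least one input;
    ``n_contributing`` records how many inputs contributed per entry.
    ``level`` must be ``"participant"`` (averaging avalanche TMs) or
    ``"group"`` (averaging participant TMs).

    ``undefined_as_zero`` is a sensitivity option that scores an undefined
    input entry as 0 (dividing by the number of inputs rather than the
    number of defined inputs); it conflates "never an ancestor" with
    "ancestor never followed" and is off by default.
    """
    if level not in ("participant", "group"):
        raise ParameterError("aggregation level must be 'participant' or 'group'")
    if not tms:
        raise ParameterError("cannot aggregate an empty list of TMs")
    below = "avalanche" if level == "participant" else "participant"
    n = tms[0].n_regions
    labels = list(tms[0].region_labels)
    for tm in tms:
        if tm.n_regions != n or list(tm.region_labels) != labels:
            raise ParameterError("all TMs must share one region set")
        if tm.level != below:
            raise ParameterError(
                f"aggregating to {level!r} requires {below!r}-level inputs, "
                f"got {tm.level!r}"
            )
    stack = np.stack([tm.probs for tm in tms])
    defined = ~np.isnan(stack)
    counts = defined.sum(axis=0)
    total = np.where(defined, np.nan_to_num(stack), 0.0).sum(axis=0)
    probs = np.full((n, n), np.nan)
    mask = counts > 0
    if undefined_as_zero:
        probs[mask] = total[mask] / len(tms)
    else:
        probs[mask] = total[mask] / counts[mask]
    return TransitionMatrix(
        probs=probs, level=level, n_contributing=counts, region_labels=labels
    )


def symmetrize_probs(probs: np.ndarray) -> np.ndarray:
    """NaN-aware symmetrization: mean of the defined members of each
    {(i, j), (j, i)} pair; NaN only where both are undefined."""
    p, pt = probs, probs.T
    both = ~np.isnan(p) & ~np.isnan(pt)
    out = np.where(both, 0.5 * (p + pt), np.where(np.isnan(p), pt, p))
    return out


def symmetrize(tm: TransitionMatrix) -> TransitionMatrix:
    """Symmetrize a TM by averaging each entry with its transpose.

    One-sided entries (defined in only one direction) take the defined
    value; entries undefined in both directions stay undefined.
    """
    if tm.symmetrized:
        raise ParameterError("TM is already symmetrized")
    return TransitionMatrix(
        probs=symmetrize_probs(tm.probs),
        level=tm.level,
        symmetrized=True,
        n_contributing=tm.n_contributing,
        region_labels=tm.region_labels,
    )


def long_delay_matrix(av: Avalanche) -> np.ndarray:
    """Binary starter-to-recruit matrix of one avalanche.

    Entry (i, j) is 1 iff region i is active in the first bin and region j
    is active at any later bin; rows of non-starters are all zero.
    """
    if av.duration < 2:
        raise UndefinedEstimateError(
            "long-delay TM undefined for avalanches of duration < 2"
        )
    starters = av.raster[:, 0].astype(float)
    recruited = av.raster[:, 1:].any(axis=1).astype(float)
    return np.outer(starters, recruited)


def long_delay_tm(avalanches: list[Avalanche]) -> TransitionMatrix:
    """Long-delay binary TM averaged over avalanches, then symmetrized.

    For one avalanche the matrix entry (i, j) is 1 if region i started the
    avalanche (active in its first bin) and region j was recruited at any
    later bin, and 0 otherwise.  Considering delays as long as the
    avalanche itself minimizes the influence of short delays, so zero-lag
    (field spread) co-activation cannot contribute.
    """
    if not avalanches:
        raise ParameterError("need at least one avalanche")
    mean = np.mean([long_delay_matrix(av) for av in avalanches], axis=0)
    return TransitionMatrix(
        probs=symmetrize_probs(mean), level="group", symmetrized=True
    )


def bandpass(ts: np.ndarray, fs: float, band: BandSpec | str) -> np.ndarray:
    """Fourth-order Butterworth band-pass, applied forward-backward.

    Zero-phase application preserves the timing of amplitude excursions,
    which is what the downstream thresholding measures.  ``band`` may be a
    :class:`BandSpec` or a canonical band name; ``"broadband"`` returns the
    input unchanged.
    """
    if isinstance(band, str):
        if band not in BANDS:
            raise ParameterError(f"unknown band {band!r}")
        band = BANDS[band]
    if band is None:
        return np.asarray(ts, dtype=float)
    if not band.high < fs / 2:
        raise ParameterError(
            f"band edge {band.high} Hz violates Nyquist at fs={fs} Hz"
        )
    sos = butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=1)
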