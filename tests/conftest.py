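"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive loops so they stay independent of the
vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from avaconn.types import Avalanche


@pytest.fixture
def toy_tm_avalanche() -> Avalanche:
    """The worked transition-matrix example: region 0 is active in three
    bins (never the last), region 1 follows it in two of the three, so the
    (0, 1) transition probability must be exactly 2/3."""
    raster = np.array(
        [
            [1, 1, 1, 0],  # region i: ancestors in bins 0,1,2
            [0, 1, 1, 0],  # region j: follows i after bins 0 and 1, not 2
            [0, 0, 0, 1],  # keeps the final bin non-quiescent
        ],
        dtype=bool,
    )
    return Avalanche(raster=raster)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_raster(rng, n_regions=10, n_bins=200, p_active=0.25) -> np.ndarray:
    """Sparse random boolean raster with quiescent gaps."""
    return rng.random((n_regions, n_bins)) < p_active


# ---------------------------------------------------------------- oracles


def brute_force_avalanche_spans(active: np.ndarray, min_duration: int):
    """Naive scan for maximal runs of bins with any activity."""
    spans = []
    start = None
    for t in range(active.shape[1]):
        if active[:, t].any():
            if start is None:
                start = t
        else:
            if start is not None:
                spans.append((start, t - 1))
                start = None
    if start is not None:
        spans.append((start, active.shape[1] - 1))
    return [(s, e) for s, e in spans if e - s + 1 >= min_duration]


def brute_force_tm(raster: np.ndarray):
    """Naive pair-counting transition probabilities of one avalanche."""
    n, dur = raster.shape
    probs = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        den = 0
        num = np.zeros(n, dtype=int)
        for t in range(dur - 1):
            if raster[i, t]:
                den += 1
                for j in range(n):
                    if raster[j, t + 1]:
                        num[j] += 1
        if den > 0:
            probs[i] = num / den
            counts[i] = num
    return probs, counts


def brute_force_long_delay(rasters):
    """Naive starter-to-recruit binary matrices, averaged."""
    n = rasters[0].shape[0]
    acc = np.zeros((n, n))
    for r in rasters:
        m = np.zeros((n, n))
        for i in range(n):
            if r[i, 0]:
                for j in range(n):
                    if r[j, 1:].any():
                        m[i, j] = 1.0
        acc += m
    return acc / len(rasters)


def brute_force_transition_freq(rasters, n_regions):
    """Naive i->j consecutive-bin co-activation counts over cascades."""
    counts = np.zeros((n_regions, n_regions))
    for r in rasters:
        for t in range(r.shape[1] - 1):
            for i in np.flatnonzero(r[:, t]):
                for j in np.flatnonzero(r[:, t + 1]):
                    counts[i, j] += 1
    return counts


def spearman_by_hand(x, y):
    """Average-rank Spearman via explicit rank construction."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
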