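"""Core value types shared across the avalanche pipeline.

The pipeline moves through a small set of containers: continuous
multichannel series are z-scored (:class:`ZScoredSeries`), thresholded and
binned into a :class:`BinarizedRaster`, cut into :class:`Avalanche` cascades,
summarized into :class:`TransitionMatrix` objects, and finally compared to a
:class:`StructuralConnectome` yielding a :class:`CouplingResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "StructuralConnectome",
    "ZScoredSeries",
    "BinarizedRaster",
    "Avalanche",
    "BranchingEstimate",
    "TransitionMatrix",
    "BandSpec",
    "BANDS",
    "EdgeVector",
    "CouplingResult",
    "CascadeGroundTruth",
    "SurrogateSpec",
]


def _default_labels(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative region-by-region weight matrix.

    Weights are streamline-count-like: unitless, heavy-tailed, zero on the
    diagonal.
    """

    weights: np.ndarray
    region_labels: Sequence[str] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError("connectome weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ParameterError("connectome weights must be symmetric")
        if (w < 0).any():
            raise ParameterError("connectome weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.region_labels is None:
            self.region_labels = _default_labels(w.shape[0])
        elif len(self.region_labels) != w.shape[0]:
            raise ParameterError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ZScoredSeries:
    """Per-region standardized series (mean 0, population SD 1)."""

    values: np.ndarray
    fs: float
    region_labels: Sequence[str] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("values must be a regions x samples matrix")
        if self.region_labels is None:
            self.region_labels = _default_labels(self.values.shape[0])

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class BinarizedRaster:
    """Boolean regions x time-bins activity array.

    ``active[i, b]`` is True when region ``i`` had at least one
    suprathreshold sample inside bin ``b``.
    """

    active: np.ndarray
    bin_size: int
    fs: float
    threshold: float

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.ndim != 2:
            raise ParameterError("active must be a regions x bins matrix")
        if self.bin_size < 1:
            raise ParameterError("bin_size must be >= 1")
        if self.threshold <= 0:
            raise ParameterError("threshold must be positive")

    @property
    def n_regions(self) -> int:
        return self.active.shape[0]

    @property
    def n_bins(self) -> int:
        return self.active.shape[1]


@dataclass
class Avalanche:
    """One contiguous cascade of activity.

    ``raster`` is the regions x duration boolean slice; ``events_per_bin``
    holds the event count of each bin.  For raster-derived avalanches the
    count is the number of active regions per bin; generator-produced
    avalanches may carry pre-collapse event counts (several events of one
    region in one bin count individually there).
    """

    raster: np.ndarray
    start_bin: int = 0
    end_bin: int = None
    events_per_bin: np.ndarray = None
    truncated: bool = False

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2 or self.raster.shape[1] < 1:
            raise ParameterError("raster must be a regions x duration matrix")
        if not self.raster.any(axis=0).all():
            raise ParameterError("every bin of an avalanche must have >=1 active region")
        if self.end_bin is None:
            self.end_bin = self.start_bin + self.raster.shape[1] - 1
        if self.events_per_bin is None:
            self.events_per_bin = self.raster.sum(axis=0)
        self.events_per_bin = np.asarray(self.events_per_bin, dtype=np.int64)
        if self.events_per_bin.shape[0] != self.raster.shape[1]:
            raise ParameterError("events_per_bin must have one entry per bin")
        if (self.events_per_bin < 1).any():
            raise ParameterError("events_per_bin entries must be >= 1")

    @property
    def duration(self) -> int:
        """Number of time bins spanned by the avalanche."""
        return self.raster.shape[1]

    @property
    def size(self) -> int:
        """Number of distinct regions recruited at least once."""
        return int(self.raster.any(axis=1).sum())

    @property
    def n_events(self) -> int:
        """Total event count across bins (pre-collapse where available)."""
        return int(self.events_per_bin.sum())


@dataclass
class BranchingEstimate:
    """Branching parameter of a set of avalanches.

    ``sigma`` is the geometric mean over avalanches of the per-avalanche
    ``sigma_per_avalanche`` values; only avalanches of duration >= 2
    contribute.
    """

    sigma_per_avalanche: np.ndarray
    sigma: float
    n_avalanches: int


@dataclass
class TransitionMatrix:
    """Conditional-activation probabilities between regions.

    ``probs[i, j]`` estimates P(region j active at t+delta | region i active
    at t) within avalanches, with delta equal to one time bin (the
    long-delay variant relaxes this).  Entries that are not estimable (the
    region was never an ancestor) are NaN and excluded from ``defined_mask``.
    """

    probs: np.ndarray
    level: str = "avalanche"
    symmetrized: bool = False
    ancestor_counts: Optional[np.ndarray] = None
    n_contributing: Optional[np.ndarray] = None
    region_labels: Sequence[str] = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise ParameterError("probs must be a square matrix")
        if self.level not in ("avalanche", "participant", "group"):
            raise ParameterError(f"unknown TM level: {self.level!r}")
        defined = ~np.isnan(self.probs)
        vals = self.probs[defined]
        if vals.size and ((vals < -1e-12).any() or (vals > 1 + 1e-12).any()):
            raise ParameterError("defined TM entries must lie in [0, 1]")
        if self.region_labels is None:
            self.region_labels = _default_labels(self.probs.shape[0])

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.probs)

    @property
    def n_regions(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class BandSpec:
    """A canonical frequency band (edges in Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 <= self.low < self.high):
            raise ParameterError("band edges must satisfy 0 <= low < high")


#: Canonical band edges.  ``broadband`` means no additional filtering.
BANDS = {
    "broadband": None,
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 48.0),
}


@dataclass
class EdgeVector:
    """Off-diagonal upper-triangle values of a symmetric matrix.

    ``pair_index`` lists the (i, j) region pairs (i < j, row-major order)
    corresponding to each value; two vectors entering a correlation must
    share it.
    """

    values: np.ndarray
    pair_index: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.pair_index):
            raise ParameterError("values and pair_index must have equal length")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class CouplingResult:
    """Observed TM-connectome correlation with its permutation null.

    ``p_value`` is the plain proportion of null correlations >= the
    observed one (no continuity correction); when the proportion is zero
    the result can only be stated as p < 1/n_perm, see :meth:`p_report`.
    """

    r_observed: float
    null_rs: np.ndarray
    p_value: float
    n_perm: int
    seed: Optional[int] = None
    n_edges: Optional[int] = None

    def p_report(self) -> str:
        """Human-readable p-value honouring the 1/n_perm resolution."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


@dataclass
class CascadeGroundTruth:
    """Known-truth cascades from the connectome-coupled generator."""

    rasters: list
    coupling: float
    sigma_target: float
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ParameterError("coupling must lie in [0, 1]")

    @property
    def n_cascades(self) -> int:
        return len(self.rasters)


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of the leadfield-mixing (field spread) surrogate.

    Defaults reproduce the uncoupled surrogate construction: 66 smoothed
    white-noise sources, 100 non-overlapping single-region perturbations of
    length 5, 10 or 100 samples and amplitude 50-400, separated by at least
    200 samples, mixed to sensors and re-extracted at SNR 4.
    """

    n_sources: int = 66
    n_perturbations: int = 100
    perturbation_lengths: tuple = (5, 10, 100)
    amplitude_range: tuple = (50.0, 400.0)
    min_separation: int = 200
    snr: float = 4.0
    smoothing_window: int = 21
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_sources < 1 or self.n_perturbations < 0:
            raise ParameterError("n_sources must be >= 1, n_perturbations >= 0")
        if self.min_separation < max(self.perturbation_lengths):
            raise ParameterError("min_separation must be >= the longest perturbation")
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ParameterError("amplitude_range must be a positive interval")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
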