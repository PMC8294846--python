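"""Synthetic-data generators with known ground truth.

Nothing here is fitted to real recordings: the generators exist so that
every downstream estimator (avalanche extraction, branching parameter,
transition matrices, structure-function coupling) can be exercised against
inputs whose generating mechanism is known exactly.

Generators
----------
``gen_connectome``
    Random symmetric streamline-count-like weight matrix.
``simulate_cascades``
    Cascades whose spread is biased toward strong structural edges by a
    tunable ``coupling`` in [0, 1] (0 = spread ignores the connectome).
``embed_continuous``
    Continuous multichannel series with cascades embedded as suprathreshold
    pulses riding on smoothed noise, for round-trip detection tests.
``simulate_branching_process``
    Galton-Watson process with Poisson offspring; critical at sigma = 1.
``gen_leadfield_surrogate``
    Uncoupled sources mixed linearly to sensors and re-extracted, the
    field-spread control: any TM structure it produces reflects linear
    mixing, not an underlying connectome.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    DegenerateGeneratorError,
    ParameterError,
    PlacementError,
)
from .types import (
    Avalanche,
    CascadeGroundTruth,
    StructuralConnectome,
    SurrogateSpec,
)

__all__ = [
    "gen_connectome",
    "simulate_cascades",
    "embed_continuous",
    "simulate_branching_process",
    "gen_leadfield_surrogate",
]

#: Noise excursions are limited to this many SDs (after smoothing and
#: re-standardization) so that, at the default |z| > 3 threshold,
#: detections are attributable to embedded events.
_NOISE_CLIP_SD = 2.8


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_connectome(
    n_regions: int,
    density: float = 0.3,
    weight_dispersion: float = 1.0,
    seed: Optional[int] = None,
) -> StructuralConnectome:
    """Generate a random streamline-count-like structural connectome.

    Off-diagonal edges exist independently with probability ``density``;
    existing edges carry log-normal weights (heavy-tailed, like streamline
    counts) with log-SD ``weight_dispersion``.  At least one positive edge
    is guaranteed.
    """
    if n_regions < 2:
        raise ParameterError("n_regions must be >= 2")
    if not 0 < density <= 1:
        raise ParameterError("density must lie in (0, 1]")
    if weight_dispersion <= 0:
        raise ParameterError("weight_dispersion must be positive")
    rng = _rng(seed)
    n_pairs = n_regions * (n_regions - 1) // 2
    present = rng.random(n_pairs) < density
    weights = np.where(
        present, rng.lognormal(mean=0.0, sigma=weight_dispersion, size=n_pairs), 0.0
    )
    if not present.any():
        # guarantee a connected pair even at tiny densities
        weights[rng.integers(n_pairs)] = rng.lognormal(0.0, weight_dispersion)
    w = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    w[iu] = weights
    w += w.T
    return StructuralConnectome(weights=w)


def _spread_probabilities(
    sc: StructuralConnectome, coupling: float, sigma_target: float
) -> np.ndarray:
    """Per-step activation probabilities P[i, j].

    Each active region i independently activates j != i with probability
    sigma_target * u_ij, where u_i. mixes the row-normalized structural
    weights with a uniform kernel: u_ij = coupling * w_ij / sum_k w_ik +
    (1 - coupling) / (n - 1).  Rows of u sum to 1 (except zero-degree rows
    at coupling = 1), so the expected offspring per active region equals
    sigma_target.
    """
    n = sc.n_regions
    w = sc.weights
    rowsum = w.sum(axis=1, keepdims=True)
    if coupling == 1.0 and not (rowsum > 0).any():
        raise DegenerateGeneratorError(
            "all-zero connectome with coupling=1 cannot spread"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        wn = np.where(rowsum > 0, w / rowsum, 0.0)
    uniform = (np.ones((n, n)) - np.eye(n)) / (n - 1)
    u = coupling * wn + (1.0 - coupling) * uniform
    p = sigma_target * u
    if (p > 1).any():
        warnings.warn(
            "sigma_target too large for some edges; probabilities clipped at 1",
            stacklevel=3,
        )
        p = np.minimum(p, 1.0)
    return p


def simulate_cascades(
    sc: StructuralConnectome,
    coupling: float,
    sigma_target: float = 1.0,
    n_cascades: int = 1000,
    max_duration: int = 100,
    seed: Optional[int] = None,
) -> CascadeGroundTruth:
    """Simulate cascades whose spread is biased by the connectome.

    Each cascade starts from one uniformly chosen region.  At every step,
    every active region i activates each other region j independently with
    probability proportional to ``coupling * w_ij + (1 - coupling) *
    uniform``, scaled so the expected number of descendants per active
    region is ``sigma_target``.  Multiple activations of one region in a
    bin collapse to a single active entry.  A cascade ends when no region
    activates or after ``max_duration`` bins.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling must lie in [0, 1]")
    if sigma_target < 0:
        raise ParameterError("sigma_target must be >= 0")
    if n_cascades < 1 or max_duration < 1:
        raise ParameterError("n_cascades and max_duration must be >= 1")
    p = _spread_probabilities(sc, coupling, sigma_target)
    log_q = np.log1p(-p)  # log of per-pair miss probability
    n = sc.n_regions
    rng = _rng(seed)
    rasters = []
    for _ in range(n_cascades):
        active = np.zeros(n, dtype=bool)
        active[rng.integers(n)] = True
        cols = [active.copy()]
        for _ in range(max_duration - 1):
            # P(j activates) = 1 - prod over active i of (1 - p_ij)
            miss = log_q[active].sum(axis=0)
            p_next = -np.expm1(miss)
            nxt = rng.random(n) < p_next
            if not nxt.any():
                break
            cols.append(nxt)
            active = nxt
        rasters.append(np.column_stack(cols))
    return CascadeGroundTruth(
        rasters=rasters, coupling=coupling, sigma_target=sigma_target, seed=seed
    )


def embed_continuous(
    cascades: CascadeGroundTruth,
    bin_size: int = 3,
    fs: float = 1024.0,
    event_amplitude: float = 5.0,
    noise_smoothing: int = 20,
    seed: Optional[int] = None,
    gap_bins: int = 4,
    max_duty_cycle: float = 0.01,
) -> np.ndarray:
    """Embed ground-truth cascades into a continuous multichannel series.

    The background is smoothed, unit-variance, amplitude-limited noise (its
    excursions stay below the default detection threshold; see module
    note), and each ground-truth event adds a constant pulse of
    ``event_amplitude`` (in baseline-SD units) spanning its bin.  Cascades
    are placed on the binning grid and separated by at least ``gap_bins``
    quiet bins (>= 2 bins, so detection can never merge them); gaps are
    widened as needed so no region is active in more than
    ``max_duty_cycle`` of the recording, which keeps the z-score scale
    close to the noise scale and makes embedded pulses of amplitude >= 10
    exactly recoverable by the default detection chain.

    Returns a regions x samples real matrix.
    """
    if event_amplitude <= 0:
        raise ParameterError("event_amplitude must be positive")
    if bin_size < 1 or noise_smoothing < 1:
        raise ParameterError("bin_size and noise_smoothing must be >= 1")
    if gap_bins < 2:
        raise ParameterError("gap_bins must be >= 2 to keep cascades separable")
    if not 0 < max_duty_cycle <= 1:
        raise ParameterError("max_duty_cycle must lie in (0, 1]")
    rasters = cascades.rasters
    if rasters:
        n_regions = rasters[0].shape[0]
        busiest = max(
            int(sum(r[i].sum() for r in rasters)) for i in range(n_regions)
        )
    else:
        n_regions, busiest = 1, 0
    sum_dur = sum(r.shape[1] for r in rasters)
    n_gaps = len(rasters) + 1
    target_bins = int(np.ceil(busiest / max_duty_cycle)) if busiest else 0
    gap = max(gap_bins, -(-(target_bins - sum_dur) // n_gaps))
    total_bins = gap + sum(r.shape[1] + gap for r in rasters)
    total_bins = max(total_bins, 64)  # floor so pure-noise output is usable
    n_samples = total_bins * bin_size
    rng = _rng(seed)
    noise = rng.standard_normal((n_regions, n_samples))
    if noise_smoothing > 1:
        kernel = np.ones(noise_smoothing) / noise_smoothing
        noise = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="same"), 1, noise
        )
    noise /= noise.std(axis=1, keepdims=True)
    np.clip(noise, -_NOISE_CLIP_SD, _NOISE_CLIP_SD, out=noise)
    noise /= noise.std(axis=1, keepdims=True)
    signal = noise
    b = gap
    for raster in rasters:
        dur = raster.shape[1]
        for j in range(dur):
            cols = slice((b + j) * bin_size, (b + j + 1) * bin_size)
            signal[raster[:, j], cols] += event_amplitude
        b += dur + gap
    return signal


def simulate_branching_process(
    sigma: float,
    n_avalanches: int,
    n_regions: int = 64,
    max_events: int = 10_000,
    seed: Optional[int] = None,
) -> list[Avalanche]:
    """Simulate Galton-Watson avalanches with Poisson offspring.

    Each avalanche starts from a single ancestor event in bin 1; every
    event in bin t spawns Poisson(``sigma``) events in bin t+1, each placed
    in a uniformly random region.  The process stops at extinction or once
    the cumulative event count reaches ``max_events`` (such avalanches are
    flagged ``truncated``).  The returned avalanches carry the
    pre-collapse event counts in ``events_per_bin`` while their boolean
    rasters collapse duplicate (region, bin) events.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if n_regions < 1 or n_avalanches < 1:
        raise ParameterError("n_regions and n_avalanches must be >= 1")
    rng = _rng(seed)
    avalanches = []
    for _ in range(n_avalanches):
        counts = [1]
        cols = [np.isin(np.arange(n_regions), rng.integers(n_regions))]
        total = 1
        truncated = False
        while True:
            k = rng.poisson(sigma * counts[-1])
            if k == 0:
                break
            regions = rng.integers(n_regions, size=k)
            col = np.zeros(n_regions, dtype=bool)
            col[regions] = True
            counts.append(k)
            cols.append(col)
            total += k
            # stop once the cap is reached; the generation just appended is
            # complete but never reproduces, hence the truncated flag
            if total >= max_events:
                truncated = True
                break
        avalanches.append(
            Avalanche(
                raster=np.column_stack(cols),
                events_per_bin=np.asarray(counts),
                truncated=truncated,
            )
        )
    return avalanches


def _place_perturbations(
    spec: SurrogateSpec, n_samples: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw non-overlapping perturbations respecting min_separation.

    Placement is exact (no rejection loop): lengths are drawn first, the
    remaining slack is split into random gaps, and onsets follow.
    """
    k = spec.n_perturbations
    if k == 0:
        return pd.DataFrame(columns=["region", "onset_sample", "length", "amplitude"])
    lengths = rng.choice(spec.perturbation_lengths, size=k)
    occupied = int(lengths.sum()) + (k - 1) * spec.min_separation
    slack = n_samples - occupied
    if slack < 0:
        raise PlacementError(
            f"{k} perturbations need >= {occupied} samples, got {n_samples}"
        )
    cuts = np.sort(rng.random(k)) * slack
    onsets = np.floor(cuts).astype(int) + np.concatenate(
        ([0], np.cumsum(lengths[:-1] + spec.min_separation))
    )
    lo, hi = spec.amplitude_range
    return pd.DataFrame(
        {
            "region": rng.integers(spec.n_sources, size=k),
            "onset_sample": onsets,
            "length": lengths.astype(int),
            "amplitude": rng.uniform(lo, hi, size=k),
        }
    )


def _fibonacci_cap(n: int, radius: float, z_min: float) -> np.ndarray:
    """Quasi-uniform points on the spherical cap z >= z_min*radius."""
    i = np.arange(n) + 0.5
    z = 1 - (1 - z_min) * i / n  # uniform in z over the cap
    azim = np.pi * (1 + np.sqrt(5.0)) * i
    r_xy = np.sqrt(1 - z**2)
    return radius * np.column_stack(
        [r_xy * np.cos(azim), r_xy * np.sin(azim), z]
    )


def _sensor_geometry(
    n_sensors: int, n_sources: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random sensor positions on a hemispheric cap (radius 1) and
    well-separated source positions on an interior cap shell (radius 0.85,
    jittered) inside the sensor coverage.  Keeping every source close to
    sensors keeps the linear inverse well conditioned, so embedded
    perturbations remain attributable to their source."""
    z = rng.uniform(0.0, 1.0, n_sensors)
    phi = rng.uniform(0, 2 * np.pi, n_sensors)
    r_xy = np.sqrt(1 - z**2)
    sensors = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    sources = _fibonacci_cap(n_sources, 0.85, z_min=0.1)
    sources += 0.02 * rng.standard_normal(sources.shape)
    return sensors, sources


def gen_leadfield_surrogate(
    spec: SurrogateSpec,
    n_sensors: int = 120,
    n_samples: int = 30_000,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate the field-spread surrogate dataset.

    White Gaussian source processes are smoothed with a zero-phase
    polynomial (Savitzky-Golay) filter, boxcar perturbations are added one
    region at a time per ``spec``, the sources are mixed to sensors by a
    random 1/distance leadfield, spatially correlated sensor noise
    (correlation falling off as 1/distance between sensors) is added at
    ``spec.snr``, and sources are re-extracted with a regularized linear
    inverse of the same leadfield.

    Returns ``(sensor_series, reconstructed_sources, perturbation_log)``.
    """
    if n_sensors < spec.n_sources:
        raise ParameterError("need at least as many sensors as sources")
    rng = _rng(spec.seed)
    # --- sources: smoothed white noise + boxcar perturbations
    sources = rng.standard_normal((spec.n_sources, n_samples))
    window = min(spec.smoothing_window | 1, n_samples - 1)  # odd window
    sources = savgol_filter(sources, window_length=window, polyorder=3, axis=1)
    log = _place_perturbations(spec, n_samples, rng)
    for row in log.itertuples(index=False):
        sources[row.region, row.onset_sample : row.onset_sample + row.length] += (
            row.amplitude
        )
    # --- leadfield mixing: gain / distance(sensor, source)
    sensors_pos, sources_pos = _sensor_geometry(n_sensors, spec.n_sources, rng)
    dist = np.linalg.norm(
        sensors_pos[:, None, :] - sources_pos[None, :, :], axis=2
    )
    gains = rng.uniform(0.5, 1.5, size=spec.n_sources)
    leadfield = gains[None, :] / np.maximum(dist, 0.05)
    sensor_clean = leadfield @ sources
    # --- spatially correlated sensor noise at the requested SNR
    sdist = np.linalg.norm(sensors_pos[:, None, :] - sensors_pos[None, :, :], axis=2)
    corr = 1.0 / np.maximum(sdist, 0.1)
    corr /= corr.max()
    np.fill_diagonal(corr, 1.0)
    # eigen-clip to the nearest PSD correlation structure
    vals, vecs = np.linalg.eigh(corr)
    chol = vecs * np.sqrt(np.maximum(vals, 1e-9))[None, :]
    noise = chol @ rng.standard_normal((n_sensors, n_samples))
    sig_sd = sensor_clean.std(axis=1, keepdims=True)
    noise *= sig_sd / (np.sqrt(spec.snr) * noise.std(axis=1, keepdims=True))
    sensor_series = sensor_clean + noise
    # --- regularized linear inverse (Tikhonov) of the known leadfield
    gram = leadfield.T @ leadfield
    lam = 1e-6 * np.trace(gram) / gram.shape[0]
    inverse = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), leadfield.T)
    reconstructed = inverse @ sensor_series
    return sensor_series, reconstructed, log


def cascades_to_avalanches(cascades: CascadeGroundTruth) -> list[Avalanche]:
    """View ground-truth cascade rasters as Avalanche objects."""
    return [Avalanche(raster=r) for r in cascades.rasters]
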