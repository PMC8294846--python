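"""Structure-function coupling statistics and the permutation null.

The headline quantity is the Spearman rank correlation between the
edge-wise entries of a (symmetrized) transition matrix and the
corresponding structural connectome weights.  Its null distribution is
built by permuting the temporal order of bins within every avalanche --
which preserves each bin's active-region set, hence all purely spatial
statistics -- and rebuilding the full aggregated TM per permutation.  The
p-value is the plain proportion of null correlations at least as large as
the observed one.

The module also provides the discrete maximum-likelihood power-law fit
used to check the avalanche size distribution (critical branching predicts
an exponent of -3/2).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .errors import ParameterError, UndefinedEstimateError
from .transitions import symmetrize_probs
from .types import Avalanche, CouplingResult, EdgeVector, StructuralConnectome

__all__ = [
    "edge_vectorize",
    "spearman",
    "randomize_avalanche",
    "permutation_test",
    "fit_powerlaw_exponent",
    "select_xmin",
]


def edge_vectorize(m: np.ndarray, mask: Optional[np.ndarray] = None) -> EdgeVector:
    """Extract the off-diagonal upper-triangle entries of a symmetric matrix.

    Pairs are enumerated in row-major order (0,1), (0,2), ... ; entries
    masked out (or NaN) are dropped, and the identical pairs must be
    dropped from any partner vector before correlating (enforced by
    :func:`spearman` through the pair index).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError("matrix must be square")
    finite = np.isfinite(m) & np.isfinite(m.T)
    if not np.allclose(m[finite], m.T[finite], atol=1e-8):
        raise ParameterError("matrix must be symmetric where defined")
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = ~np.isnan(m[iu, ju])
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)[iu, ju]
    return EdgeVector(
        values=m[iu[keep], ju[keep]],
        pair_index=list(zip(iu[keep].tolist(), ju[keep].tolist())),
    )


def spearman(x: EdgeVector, y: EdgeVector) -> float:
    """Spearman rank correlation of two matched edge vectors.

    Ties receive average ranks (the correlation is the Pearson correlation
    of the rank vectors).  Raises if the pair indices differ or either
    vector is constant.
    """
    if x.pair_index != y.pair_index:
        raise ParameterError("edge vectors must share an identical pair index")
    if len(x) < 3:
        raise ParameterError("need at least 3 edge pairs")
    if np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
        raise UndefinedEstimateError("correlation undefined for a constant vector")
    r, _ = stats.spearmanr(x.values, y.values)
    return float(r)


def randomize_avalanche(av: Avalanche, rng) -> Avalanche:
    """Permute an avalanche's time bins uniformly at random.

    Each bin's set of active regions travels with the bin, so the
    randomization destroys temporal transition structure while preserving
    all spatial attributes.  Duration, size and the recorded per-bin event
    counts are carried over unchanged (the count sequence keeps its
    original order, so every scalar avalanche statistic -- including the
    branching parameter -- of the null ensemble matches the observed
    ensemble exactly).
    """
    if av.duration < 2:
        raise ParameterError("randomization needs duration >= 2")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(av.duration)
    return Avalanche(
        raster=av.raster[:, perm],
        start_bin=av.start_bin,
        end_bin=av.end_bin,
        events_per_bin=av.events_per_bin.copy(),
        truncated=av.truncated,
    )


def _as_rasters(avalanches: Iterable) -> list[np.ndarray]:
    out = []
    for av in avalanches:
        r = av.raster if isinstance(av, Avalanche) else np.asarray(av, dtype=bool)
        if r.shape[1] >= 2:
            out.append(r.astype(np.float64))
    return out


def _normalize_groups(avalanches: Sequence) -> list[list[np.ndarray]]:
    """Accept a flat avalanche list or a per-participant list of lists."""
    if len(avalanches) and isinstance(avalanches[0], (list, tuple)):
        groups = [_as_rasters(g) for g in avalanches]
    else:
        groups = [_as_rasters(avalanches)]
    return [g for g in groups if g]


def _mean_tm(rasters: list[np.ndarray], n: int) -> np.ndarray:
    """Mean avalanche TM (NaN where no avalanche defines an entry)."""
    total = np.zeros((n, n))
    count = np.zeros(n)
    for r in rasters:
        a = r[:, :-1]
        num = a @ r[:, 1:].T
        den = a.sum(axis=1)
        rows = den > 0
        total[rows] += num[rows] / den[rows, None]
        count += rows
    probs = np.full((n, n), np.nan)
    rows = count > 0
    probs[rows] = total[rows] / count[rows, None]
    return probs


def _mean_long_delay(rasters: list[np.ndarray], n: int) -> np.ndarray:
    """Mean binary starter-to-recruit matrix over avalanches."""
    total = np.zeros((n, n))
    for r in rasters:
        total += np.outer(r[:, 0], r[:, 1:].any(axis=1))
    return total / len(rasters)


def _group_probs(groups: list[list[np.ndarray]], n: int, variant: str) -> np.ndarray:
    """Participant-then-group NaN-aware mean of per-avalanche TMs."""
    fn = _mean_tm if variant == "lagged" else _mean_long_delay
    per = np.stack([fn(g, n) for g in groups])
    defined = ~np.isnan(per)
    counts = defined.sum(axis=0)
    total = np.where(defined, per, 0.0).sum(axis=0)
    probs = np.full((n, n), np.nan)
    mask = counts > 0
    probs[mask] = total[mask] / counts[mask]
    return probs


def _edge_r(sym_probs: np.ndarray, sc_weights: np.ndarray, iu, ju) -> float:
    tm_edges = sym_probs[iu, ju]
    keep = ~np.isnan(tm_edges)
    if keep.sum() < 3:
        raise UndefinedEstimateError("fewer than 3 defined TM edges")
    r, _ = stats.spearmanr(tm_edges[keep], sc_weights[iu[keep], ju[keep]])
    if np.isnan(r):
        raise UndefinedEstimateError("correlation undefined (constant edge vector)")
    return float(r)


def permutation_test(
    avalanches: Sequence,
    sc: StructuralConnectome,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    restrict_to_nonzero: bool = False,
    variant: str = "lagged",
) -> CouplingResult:
    """Permutation test of the TM-connectome association.

    The observed statistic is the Spearman correlation between the
    aggregated, symmetrized TM and the structural weights over all defined
    off-diagonal edges (optionally restricted to edges with nonzero
    structural weight).  Each permutation shuffles the bin order of every
    avalanche independently, rebuilds the full aggregated symmetrized TM
    and recomputes the correlation; ``p = (# null r >= observed r) /
    n_perm``.

    ``avalanches`` may be a flat sequence of :class:`Avalanche` objects or
    raw boolean rasters (aggregated directly), or a list of per-participant
    lists (aggregated participant-first, then across participants).
    Avalanches of duration 1 carry no transition and are ignored.
    ``variant="long_delay"`` swaps the lag-one TM for the binary
    starter-to-recruit matrix.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if variant not in ("lagged", "long_delay"):
        raise ParameterError("variant must be 'lagged' or 'long_delay'")
    groups = _normalize_groups(avalanches)
    if not groups:
        raise ParameterError("no avalanche of duration >= 2 provided")
    n = sc.n_regions
    if groups[0][0].shape[0] != n:
        raise ParameterError("avalanche region count does not match connectome")
    iu, ju = np.triu_indices(n, k=1)
    if restrict_to_nonzero:
        keep = sc.weights[iu, ju] > 0
        iu, ju = iu[keep], ju[keep]
    observed = _edge_r(
        symmetrize_probs(_group_probs(groups, n, variant)), sc.weights, iu, ju
    )
    master = np.random.SeedSequence(seed)
    null_rs = np.empty(n_perm)
    for k, child in enumerate(master.spawn(n_perm)):
        rng = np.random.default_rng(child)
        permuted = [
            [r[:, rng.permutation(r.shape[1])] for r in g] for g in groups
        ]
        null_rs[k] = _edge_r(
            symmetrize_probs(_group_probs(permuted, n, variant)),
            sc.weights,
            iu,
            ju,
        )
    p = float(np.count_nonzero(null_rs >= observed)) / n_perm
    return CouplingResult(
        r_observed=observed,
        null_rs=null_rs,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        n_edges=iu.size,
    )


def _powerlaw_nll(alpha: float, mean_log: float, xmin: int, xmax: Optional[int]):
    z = zeta(alpha, xmin)
    if xmax is not None:
        z -= zeta(alpha, xmax + 1)
    return np.log(z) + alpha * mean_log


def fit_powerlaw_exponent(
    sizes: Sequence[int], xmin: int = 1, xmax: Optional[int] = None
) -> float:
    """Discrete ML estimate of the avalanche-size power-law exponent.

    Fits P(s) proportional to s^(-alpha) over s >= ``xmin`` (optionally
    truncated at ``xmax``, appropriate when the generator caps avalanche
    size) by maximizing the zeta-normalized likelihood.  Returns the
    exponent with the sign convention used for avalanche statistics, i.e.
    -alpha (critical branching predicts -3/2).
    """
    if xmin < 1:
        raise ParameterError("xmin must be >= 1")
    s = np.asarray(sizes)
    tail = s[s >= xmin]
    if xmax is not None:
        tail = tail[tail <= xmax]
    if tail.size < 100:
        raise UndefinedEstimateError(
            f"need >= 100 sizes >= xmin, got {tail.size}"
        )
    if np.ptp(tail) == 0:
        raise UndefinedEstimateError("degenerate tail: all sizes equal")
    mean_log = float(np.mean(np.log(tail)))
    res = minimize_scalar(
        _powerlaw_nll,
        bounds=(1.0001, 10.0),
        args=(mean_log, xmin, xmax),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return -float(res.x)


def select_xmin(
    sizes: Sequence[int],
    candidates: Optional[Sequence[int]] = None,
    xmax: Optional[int] = None,
) -> int:
    """Choose xmin by minimizing the Kolmogorov-Smirnov tail distance.

    For each candidate the exponent is fitted by ML and the KS distance
    between the empirical tail CDF and the fitted (possibly truncated)
    discrete power law is computed; the candidate with the smallest
    distance wins.  Candidates default to the unique observed sizes that
    leave at least 500 tail samples (capped at 50 candidates).
    """
    s = np.asarray(sizes)
    if candidates is None:
        uniq = np.unique(s)
        candidates = [int(u) for u in uniq if (s >= u).sum() >= 500][:50]
    if not candidates:
        raise UndefinedEstimateError("no feasible xmin candidate")
    best, best_d = None, np.inf
    for xm in candidates:
        try:
            alpha = -fit_powerlaw_exponent(s, xmin=xm, xmax=xmax)
        except UndefinedEstimateError:
            continue
        tail = np.sort(s[s >= xm])
        if xmax is not None:
            tail = tail[tail <= xmax]
        uniq = np.unique(tail)
        z0 = zeta(alpha, xm) - (zeta(alpha, xmax + 1) if xmax is not None else 0.0)
        # model CDF at u: P(S <= u) = 1 - zeta(alpha, u+1)/Z (truncated analogue)
        surv = zeta(alpha, uniq + 1) - (
            zeta(alpha, xmax + 1) if xmax is not None else 0.0
        )
        cdf_model = 1.0 - surv / z0
        ecdf = np.searchsorted(tail, uniq, side="right") / tail.size
        d = float(np.max(np.abs(ecdf - cdf_model)))
        if d < best_d:
            best, best_d = xm, d
    if best is None:
        raise UndefinedEstimateError("power-law fit failed for every candidate")
    return best
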