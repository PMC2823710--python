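"""Resampling attribution of starting confidences (Step 1 of the pipeline).

Each residue's value is repeatedly standardized within small random
sub-ensembles of the data: k = (value - mu) / sigma with mu, sigma the
population mean and standard deviation of the subset.  A calibration phase
first finds the least extreme k the global maximum and minimum can attain
(k_high, k_low) over subsets forced to contain both extremes; the per-residue
trials then map each k onto [-1, 1] through the clipped piecewise-linear
transform Gamma, and the confidence rho_i is the average Gamma over all
trials.  The construction is location- and scale-free, and by design the
residues carrying the global extremes reach rho = +1 / -1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfidenceVector, PerResidueData, ResidueKey, SamplexParams, Status

# Relative floor below which a subset standard deviation is treated as null
# (all-equal subsets give sigma ~ 1e-16 * |mu| from rounding alone).
_SIGMA_REL_TOL = 1e-12

_CHUNK = 20_000  # resampling runs per vectorized block, bounds peak memory


class DegenerateDataError(ValueError):
    """All measured values identical: no contrast to classify."""


@dataclass(frozen=True)
class SubsetStats:
    """Population mean/SD of a sub-ensemble and the standardized k of one value."""

    mu: float
    sigma: float
    k: float  # NaN when degenerate
    degenerate: bool


@dataclass(frozen=True)
class Calibration:
    """Extreme-k thresholds mapping to confidence +1 / -1."""

    k_high: float
    k_low: float

    def __post_init__(self) -> None:
        if not self.k_low < 0 < self.k_high:
            raise ValueError(f"need k_low < 0 < k_high, got {self.k_low}, {self.k_high}")


def _sigma_floor(mu: float | np.ndarray) -> float | np.ndarray:
    return _SIGMA_REL_TOL * np.maximum(1.0, np.abs(mu))


def k_factor(value: float, subset: list[float] | np.ndarray) -> SubsetStats:
    """Standardized deviation of ``value`` within ``subset`` (population sigma)."""
    arr = np.asarray(subset, dtype=float)
    if arr.size == 0:
        raise ValueError("subset must be non-empty")
    mu = float(arr.mean())
    sigma = float(arr.std())
    if sigma <= _sigma_floor(mu):
        return SubsetStats(mu=mu, sigma=0.0, k=float("nan"), degenerate=True)
    return SubsetStats(mu=mu, sigma=sigma, k=(value - mu) / sigma, degenerate=False)


def gamma(stats: SubsetStats, calib: Calibration) -> float:
    """Map a standardized k onto a confidence increment in [-1, 1].

    Degenerate subsets (null sigma) are uninformative and contribute 0.
    k at or beyond the calibrated extremes clips to +/-1; in between, the map
    is linear on each side of zero.
    """
    if stats.degenerate:
        return 0.0
    k = stats.k
    if k >= calib.k_high:
        return 1.0
    if k <= calib.k_low:
        return -1.0
    return k / calib.k_high if k >= 0 else -k / calib.k_low


def _gamma_vec(k: np.ndarray, degenerate: np.ndarray, calib: Calibration) -> np.ndarray:
    out = np.where(k >= 0, k / calib.k_high, -k / calib.k_low)
    np.clip(out, -1.0, 1.0, out=out)
    out[degenerate] = 0.0
    return out


def _draw_subsets(rng: np.random.Generator, n_runs: int, pool: int, draw: int) -> np.ndarray:
    """Indices of ``draw`` items sampled without replacement from ``pool``, per run."""
    u = rng.random((n_runs, pool))
    return np.argpartition(u, draw - 1, axis=1)[:, :draw] if draw < pool else np.tile(
        np.arange(pool), (n_runs, 1)
    )


def _subset_k(
    chosen: np.ndarray, fixed: np.ndarray, target: float
) -> tuple[np.ndarray, np.ndarray]:
    """k of ``target`` within subsets = fixed values + chosen columns, per row.

    The fixed members lead each row so that calibration (max+min forced in)
    and attribution (the residue itself forced in) evaluate identically
    composed subsets through the identical floating-point reduction.
    """
    runs = chosen.shape[0]
    full = np.empty((runs, fixed.size + chosen.shape[1]))
    full[:, : fixed.size] = fixed
    full[:, fixed.size :] = chosen
    mu = full.mean(axis=1)
    var = ((full - mu[:, None]) ** 2).mean(axis=1)
    sigma = np.sqrt(var)
    degenerate = sigma <= _sigma_floor(mu)
    safe = np.where(degenerate, 1.0, sigma)
    return (target - mu) / safe, degenerate


def calibrate_extremes(
    data: PerResidueData, params: SamplexParams, rng: np.random.Generator
) -> Calibration:
    """Find the extreme-k thresholds from subsets forced to hold both extremes.

    Runs calib_multiplier * N resampling rounds; each draws a subset of the
    configured size that always contains the global maximum and minimum value
    plus randomly selected others, and standardizes both extremes within it.
    k_high is the lowest k the maximum attains, k_low the highest k of the
    minimum — the least extreme scores the true extremes can receive, so that
    clipping at them never lets a single outlier dominate the transform.
    """
    vals = np.fromiter(data.values.values(), dtype=float)
    n = vals.size
    if n < params.min_subset_size:
        raise ValueError(f"need at least {params.min_subset_size} measured values, got {n}")
    imax, imin = int(np.argmax(vals)), int(np.argmin(vals))
    if vals[imax] == vals[imin]:
        raise DegenerateDataError("all measured values are identical")
    fixed = np.array([vals[imax], vals[imin]])
    others = np.delete(vals, [imax, imin])
    size = params.subset_size(n)
    draw = size - 2
    total = params.calib_multiplier * n
    k_high, k_low = np.inf, -np.inf
    done = 0
    while done < total:
        runs = min(_CHUNK, total - done)
        chosen = others[_draw_subsets(rng, runs, others.size, draw)] if draw else np.empty((runs, 0))
        k_max, deg = _subset_k(chosen, fixed, float(fixed[0]))
        k_min, _ = _subset_k(chosen, fixed, float(fixed[1]))
        valid = ~deg
        if valid.any():
            k_high = min(k_high, float(k_max[valid].min()))
            k_low = max(k_low, float(k_min[valid].max()))
        done += runs
    if not np.isfinite(k_high) or not np.isfinite(k_low):
        raise DegenerateDataError("every calibration subset had a null standard deviation")
    return Calibration(k_high=k_high, k_low=k_low)


def attribute_confidences(
    data: PerResidueData,
    calib: Calibration,
    params: SamplexParams,
    rng: np.random.Generator,
) -> ConfidenceVector:
    """Monte-Carlo confidences for every measured residue.

    For each residue i, trial_multiplier * N subsets containing i are drawn;
    alpha_i accumulates Gamma(k_i) over the trials and rho_i = alpha_i /
    n_trial.  Missing residues receive no confidence here (Step 2 infers
    them from structural neighbors).
    """
    keys = list(data.values)
    vals = np.fromiter(data.values.values(), dtype=float)
    n = vals.size
    size = params.subset_size(n)
    draw = size - 1
    n_trial = params.trial_multiplier * n
    rho: dict[ResidueKey, float] = {}
    for i, key in enumerate(keys):
        others = np.delete(vals, i)
        fixed = vals[i : i + 1]
        alpha = 0.0
        done = 0
        while done < n_trial:
            runs = min(_CHUNK, n_trial - done)
            chosen = others[_draw_subsets(rng, runs, others.size, draw)]
            k, deg = _subset_k(chosen, fixed, float(vals[i]))
            alpha += float(_gamma_vec(k, deg, calib).sum())
            done += runs
        rho[key] = alpha / n_trial
    status = {k: Status.MEASURED for k in keys}
    return ConfidenceVector(rho=rho, status=status)


def starting_confidences(
    data: PerResidueData, params: SamplexParams, rng: np.random.Generator
) -> tuple[ConfidenceVector, Calibration]:
    """Calibrate then attribute: the full Step 1 in one call."""
    calib = calibrate_extremes(data, params, rng)
    return attribute_confidences(data, calib, params, rng), calib
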