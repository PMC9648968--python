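"""Maximum-likelihood inference of transcriptional parameters.

The likelihood of a dataset of per-cell integer observations (mature mRNA
counts n_j, or discretized transcription-site signal bins q_j) is

    L(theta) = prod_j P_model(value_j; theta),

where the model PMF is the telegraph steady state (mature data, rates
normalized by the degradation rate d) or the binned trapezoid-signal
distribution of the delay telegraph model (nascent data, absolute rates
given the known elongation time tau).  G2 cells carry two gene copies:
under the independence assumption the model PMF is the single-copy PMF
convolved with itself; under perfect allele synchrony it is the single-copy
model with doubled initiation rate.

theta = (sigma_on, sigma_off, rho) is estimated by minimizing the negative
log-likelihood over a bounded box with differential evolution followed by a
local polish; profile-likelihood scans provide confidence intervals.

Two curation schemes absorb transcription-site misidentification artifacts
in the lowest intensity bins: *fusion* merges bins 0..k-1 of both data and
model into one bin (k = 1 is a no-op), and *rejection* drops cells in bins
0..k-1 and renormalizes the model over the surviving bins (a conditional
likelihood).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import differential_evolution, minimize
from scipy.stats import chi2

from ._exceptions import (
    DataModelMismatchWarning,
    DegenerateDataWarning,
    InvalidParameterError,
)
from .model_core import convolve_pmf, derived_quantities, signal_bin_pmf, telegraph_pmf
from .types import GeneGeometry, MatureModelSpec, NascentModelSpec, RateParams

__all__ = [
    "MatureScale",
    "NascentScale",
    "ObservedDataset",
    "SearchSpace",
    "OptimizerConfig",
    "FitResult",
    "model_pmf",
    "negative_log_likelihood",
    "curate_fusion",
    "curate_rejection",
    "fit",
    "profile_likelihood_ci",
]

#: model probabilities below this floor contribute log(floor) and raise a warning
PROB_FLOOR = 1e-15

_PARAM_NAMES = ("sigma_on", "sigma_off", "rho")


@dataclass(frozen=True)
class MatureScale:
    """Timescale for mature-count fits: fixed degradation rate d (1/min).

    d is never inferred; fitted rates are interpreted relative to it.
    """

    d: float = 1.0


@dataclass(frozen=True)
class NascentScale:
    """Timescale and geometry for nascent-bin fits: fixed elongation time tau (min)."""

    tau: float = 0.5
    geometry: GeneGeometry = field(default_factory=lambda: GeneGeometry(862.0, 2200.0))


@dataclass(frozen=True)
class ObservedDataset:
    """Per-cell integer observations plus model-structure flags.

    kind: "mature" (spot counts) or "nascent" (signal bins).
    copy_mode: "one" | "independent" | "synchronized" (two-copy variants).
    curation: None, ("fusion", k) or ("rejection", k).
    """

    kind: str
    values: np.ndarray
    copy_mode: str = "one"
    curation: tuple[str, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        if self.kind not in ("mature", "nascent"):
            raise InvalidParameterError(f"unknown data kind {self.kind!r}")
        if self.copy_mode not in ("one", "independent", "synchronized"):
            raise InvalidParameterError(f"unknown copy mode {self.copy_mode!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidParameterError("values must be a non-empty 1-D integer vector")
        if np.any(self.values < 0):
            raise InvalidParameterError("observations must be non-negative integers")
        if self.curation is not None:
            method, k = self.curation
            if method not in ("fusion", "rejection"):
                raise InvalidParameterError(f"unknown curation method {method!r}")
            if k < 1:
                raise InvalidParameterError("curation threshold k must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds for (sigma_on, sigma_off, rho), 1/min.

    Defaults follow the optimizer search region used for both data kinds:
    switching rates in (0, 250), initiation rate in (0, 300).  The lower
    bound is held slightly above zero so the stationary promoter occupancy
    stays defined.
    """

    lower: tuple[float, float, float] = (1e-3, 1e-3, 1e-3)
    upper: tuple[float, float, float] = (250.0, 250.0, 300.0)

    def __post_init__(self):
        for lo, hi in zip(self.lower, self.upper):
            if not (0 <= lo < hi):
                raise InvalidParameterError("need 0 <= lower < upper for every parameter")

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return list(zip(self.lower, self.upper))

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    """Differential-evolution budget.

    ``popsize`` is the scipy per-parameter multiplier (total population is
    about 3x this).  ``maxiter`` caps generations; convergence usually stops
    the search much earlier and a local polish refines the best member.
    """

    popsize: int = 17
    maxiter: int = 10_000
    tol: float = 1e-4
    seed: int = 0
    restarts: int = 1
    polish: bool = True
    eps: float = 1e-8

    def scaled(self, budget: float) -> "OptimizerConfig":
        """Scale population and iteration budget (for smoke/benchmark runs)."""
        return replace(
            self,
            popsize=max(4, int(self.popsize * budget)),
            maxiter=max(20, int(self.maxiter * budget)),
        )


@dataclass
class FitResult:
    """Point estimate with likelihood value, optimizer metadata and derived quantities."""

    theta_star: RateParams
    nll: float
    iterations: int
    n_evaluations: int
    seed: int
    derived: dict
    degenerate: bool = False
    ci: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "sigma_on": self.theta_star.sigma_on,
            "sigma_off": self.theta_star.sigma_off,
            "rho": self.theta_star.rho,
            "nll": self.nll,
            "iterations": self.iterations,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "derived": {
                k: (None if isinstance(v, float) and math.isinf(v) else v)
                for k, v in self.derived.items()
            },
        }
        if self.ci is not None:
            d["ci"] = self.ci
        return d

    def to_json(self, path=None, **extra):
        payload = {**self.to_dict(), **extra}
        if path is None:
            return json.dumps(payload, indent=2)
        Path(path).write_text(json.dumps(payload, indent=2))
        return None


def model_pmf(params: RateParams, kind: str, scale, copy_mode: str = "one",
              eps: float = 1e-8, min_truncation: int = 0) -> np.ndarray:
    """Model probability vector for one dataset configuration (before curation)."""
    if kind == "mature":
        if not isinstance(scale, MatureScale):
            raise InvalidParameterError("mature data require a MatureScale")
        if copy_mode == "synchronized":
            params = RateParams(params.sigma_on, params.sigma_off, 2.0 * params.rho)
        pmf = telegraph_pmf(MatureModelSpec(params, scale.d), eps=eps,
                            min_truncation=min_truncation)
    else:
        if not isinstance(scale, NascentScale):
            raise InvalidParameterError("nascent data require a NascentScale")
        if copy_mode == "synchronized":
            params = RateParams(params.sigma_on, params.sigma_off, 2.0 * params.rho)
        pmf = signal_bin_pmf(NascentModelSpec(params, scale.tau, scale.geometry),
                             eps=eps, min_truncation=min_truncation)
    if copy_mode == "independent":
        pmf = convolve_pmf(pmf, pmf)
    return pmf.probs


def curate_fusion(probs: np.ndarray, values: np.ndarray, k: int):
    """Merge bins 0..k-1 of model and data into a single fused bin.

    Returns (fused model vector, remapped data).  The fused bin is index 0 of
    the new vector; bin i >= k maps to index i - k + 1.  k = 1 is the identity.
    """
    probs = np.asarray(probs, dtype=float)
    values = np.asarray(values, dtype=np.int64)
    if k < 1:
        raise InvalidParameterError("fusion threshold k must be >= 1")
    if k > probs.size:
        raise InvalidParameterError(f"fusion threshold k={k} exceeds model support {probs.size}")
    if k == 1:
        return probs, values
    fused = np.concatenate([[probs[:k].sum()], probs[k:]])
    mapped = np.where(values < k, 0, values - k + 1)
    return fused, mapped


def curate_rejection(probs: np.ndarray, values: np.ndarray, k: int):
    """Drop data in bins 0..k-1 and renormalize the model over bins >= k.

    Returns (conditional model vector over bins k, k+1, ..., surviving data
    shifted by -k).  The conditional likelihood is the only renormalization
    consistent with discarding cells by bin.
    """
    probs = np.asarray(probs, dtype=float)
    values = np.asarray(values, dtype=np.int64)
    if k < 1:
        raise InvalidParameterError("rejection threshold k must be >= 1")
    if k >= probs.size:
        raise InvalidParameterError(f"rejection threshold k={k} leaves no model support")
    surviving = values[values >= k]
    if surviving.size == 0:
        raise InvalidParameterError("rejection curation removed every cell")
    tail = probs[k:]
    mass = tail.sum()
    if mass <= 0:
        raise InvalidParameterError("model places no mass on surviving bins")
    return tail / mass, surviving - k


def _histogram(values: np.ndarray):
    uniq, counts = np.unique(values, return_counts=True)
    return uniq, counts


def negative_log_likelihood(data: ObservedDataset, params: RateParams, scale,
                            eps: float = 1e-8) -> float:
    """-sum_j log P_model(value_j) under the dataset's copy mode and curation.

    Model probabilities below ``PROB_FLOOR`` are floored (with a
    data-model-mismatch warning) to keep the objective finite.
    """
    max_obs = int(data.values.max())
    probs = model_pmf(params, data.kind, scale, data.copy_mode, eps=eps,
                      min_truncation=max_obs + 1)
    values = data.values
    if data.curation is not None:
        method, k = data.curation
        if method == "fusion":
            probs, values = curate_fusion(probs, values, k)
        else:
            probs, values = curate_rejection(probs, values, k)
    uniq, counts = _histogram(values)
    p = np.full(uniq.size, PROB_FLOOR)
    inside = uniq < probs.size
    p[inside] = np.maximum(probs[uniq[inside]], PROB_FLOOR)
    if np.any(p <= PROB_FLOOR):
        warnings.warn(
            "some observations have model probability at the floor "
            f"({PROB_FLOOR:g}); data and model may be mismatched",
            DataModelMismatchWarning,
            stacklevel=2,
        )
    return float(-(counts * np.log(p)).sum())


def _objective(data: ObservedDataset, scale, eps: float):
    def f(theta: np.ndarray) -> float:
        params = RateParams(*np.maximum(theta, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataModelMismatchWarning)
            return negative_log_likelihood(data, params, scale, eps=eps)

    return f


def fit(data: ObservedDataset, scale, space: SearchSpace | None = None,
        optimizer: OptimizerConfig | None = None) -> FitResult:
    """Global stochastic MLE of (sigma_on, sigma_off, rho).

    Differential evolution over the bounded search box, optionally restarted
    with distinct seeds, keeping the best negative log-likelihood.
    """
    space = space or SearchSpace()
    cfg = optimizer or OptimizerConfig()
    degenerate = bool(np.all(data.values == 0))
    if degenerate:
        warnings.warn(
            "all observations are zero; rho is unidentifiable and will sit "
            "near the lower search bound",
            DegenerateDataWarning,
            stacklevel=2,
        )
    f = _objective(data, scale, cfg.eps)
    best = None
    iterations = 0
    n_eval = 0
    for r in range(max(1, cfg.restarts)):
        res = differential_evolution(
            f,
            bounds=space.bounds,
            seed=(cfg.seed + 7919 * r) % 2**31,
            popsize=cfg.popsize,
            maxiter=cfg.maxiter,
            tol=cfg.tol,
            mutation=(0.5, 1.0),
            recombination=0.7,
            polish=cfg.polish,
            updating="immediate",
        )
        iterations += int(res.nit)
        n_eval += int(res.nfev)
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(
            f"optimizer failed to reach a finite negative log-likelihood: {best}"
        )
    theta = RateParams(*space.clip(best.x))
    return FitResult(
        theta_star=theta,
        nll=float(best.fun),
        iterations=iterations,
        n_evaluations=n_eval,
        seed=cfg.seed,
        derived=derived_quantities(theta),
        degenerate=degenerate,
    )


#: half the 95% chi-square(1) quantile: profile-NLL excursion defining the CI
PROFILE_THRESHOLD_95 = float(chi2.ppf(0.95, df=1) / 2.0)  # 1.9207...


def _profile_nll(f3, space: SearchSpace, index: int, value: float, start_free: np.ndarray):
    """Minimize the NLL over the two free parameters with one parameter fixed."""
    free_idx = [i for i in range(3) if i != index]
    bounds = [space.bounds[i] for i in free_idx]

    def g(free):
        theta = np.empty(3)
        theta[index] = value
        theta[free_idx] = free
        return f3(theta)

    res = minimize(g, x0=np.clip(start_free, [b[0] for b in bounds], [b[1] for b in bounds]),
                   method="L-BFGS-B", bounds=bounds)
    return float(res.fun), res.x


def profile_likelihood_ci(data: ObservedDataset, fit_result: FitResult, param: str,
                          scale, space: SearchSpace | None = None,
                          level: float = 0.95, n_grid: int = 41) -> dict:
    """Profile-likelihood confidence interval for one parameter.

    Scans fixed values of ``param`` on a log grid spanning [theta*/10,
    10*theta*] (clipped to the search box), re-optimizing the remaining
    parameters, and returns the values whose profile NLL stays within
    chi2(level, 1)/2 of the minimum.  Endpoints are refined by bisection;
    an endpoint pinned at a search bound is flagged.
    """
    if param not in _PARAM_NAMES:
        raise InvalidParameterError(f"unknown parameter {param!r}")
    space = space or SearchSpace()
    index = _PARAM_NAMES.index(param)
    threshold_excess = float(chi2.ppf(level, df=1) / 2.0)
    f3 = _objective(data, scale, 1e-8)
    theta_hat = fit_result.theta_star.as_array()
    center = theta_hat[index]
    nll_min = fit_result.nll
    limit = nll_min + threshold_excess
    lo_bound, hi_bound = space.bounds[index]
    grid_lo = max(lo_bound, center / 10.0)
    grid_hi = min(hi_bound, center * 10.0)
    free_idx = [i for i in range(3) if i != index]
    start = theta_hat[free_idx]

    half = n_grid // 2

    def scan(values):
        """Walk outward; return (last value below limit, first above, warm start)."""
        prev_inside = center
        warm = start.copy()
        for v in values:
            nll_v, warm = _profile_nll(f3, space, index, v, warm)
            if nll_v > limit:
                return prev_inside, v, True
            prev_inside = v
        return prev_inside, None, False

    down = np.geomspace(center, grid_lo, half + 1)[1:] if grid_lo < center else []
    up = np.geomspace(center, grid_hi, half + 1)[1:] if grid_hi > center else []

    lo_in, lo_out, lo_crossed = scan(down)
    hi_in, hi_out, hi_crossed = scan(up)

    def bisect(inside, outside):
        warm = start.copy()
        for _ in range(12):
            mid = math.sqrt(inside * outside)  # log-scale midpoint
            nll_mid, warm = _profile_nll(f3, space, index, mid, warm)
            if nll_mid > limit:
                outside = mid
            else:
                inside = mid
        return inside

    lower = bisect(lo_in, lo_out) if lo_crossed else grid_lo
    upper = bisect(hi_in, hi_out) if hi_crossed else grid_hi
    return {
        "param": param,
        "level": level,
        "lower": float(lower),
        "upper": float(upper),
        "lower_at_bound": not lo_crossed,
        "upper_at_bound": not hi_crossed,
    }
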