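"""Steady-state distributions for the telegraph and delay telegraph models.

Two solvers form the numerical core:

* :func:`telegraph_pmf` — steady-state mature mRNA distribution of the
  two-state telegraph model (promoter ON/OFF switching, initiation in the ON
  state, first-order degradation), computed by finite state projection (FSP):
  the chemical master equation is truncated to a finite count range and the
  stationary distribution of the truncated generator is solved directly.

* :func:`delay_polII_pmf` — steady-state distribution of the number k of
  gene-bound Pol II under the delay telegraph model, where every initiated
  transcript resides on the gene for a fixed time tau.  Because residence is
  deterministic, k equals the number of initiation events of the
  telegraph-gated Poisson process during the last window of length tau, so
  the distribution is obtained exactly as a transient counting-process
  solution over [0, tau] started from the stationary promoter occupancy.
  The matrix exponential action is evaluated by uniformization (Jensen's
  method), which involves only non-negative terms and is therefore stable.

The trapezoidal fluorescence profile maps a Pol II at normalized gene
position x to signal q(x) = x·L/L1 for x <= L1/L and 1 beyond; under the
uniform-position assumption each bound Pol II contributes an independent
signal with density g(s) = (L1/L)·1[0,1](s) + (L2/L)·delta_1(s).  The total
signal for k bound Pol II is the k-fold convolution g*k, a binomial mixture
of shifted uniform-sum (Irwin-Hall) densities.  Its integrals over unit bins
reduce to Eulerian-number probabilities, computed here by the all-positive
recurrence — exact at integer bin edges for any k.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.special import gammaln
from scipy.stats import binom as _binom
from scipy.stats import poisson as _poisson

from ._exceptions import InvalidParameterError, TruncationError, UndefinedQuantityError
from .types import CountPMF, GeneGeometry, MatureModelSpec, NascentModelSpec, SignalBinPMF

__all__ = [
    "telegraph_pmf",
    "delay_polII_pmf",
    "signal_conditional_bin_probs",
    "signal_bin_pmf",
    "signal_mean",
    "convolve_pmf",
    "derived_quantities",
    "fano_factor",
    "telegraph_moments",
]

#: hard cap on the FSP count truncation
TRUNCATION_CAP = 100_000


def telegraph_moments(spec: MatureModelSpec) -> tuple[float, float]:
    """Closed-form stationary (mean, variance) of the telegraph model mature count."""
    r = spec.rates
    s = r.sigma_on + r.sigma_off
    if s == 0:
        # frozen promoter; conditional on the (stationary-undefined) state.
        raise UndefinedQuantityError("moments undefined when both switching rates are zero")
    mean = r.rho * r.sigma_on / s / spec.d
    fano = 1.0 + r.rho * r.sigma_off / (s * (s + spec.d))
    return mean, mean * fano


def _solve_stationary(A: sp.csr_matrix) -> np.ndarray:
    """Solve A p = 0, sum(p) = 1 for a (closed) truncated generator A (columns = source)."""
    n = A.shape[0]
    A = A.tolil()
    A[n - 1, :] = 1.0  # replace one balance equation by the normalization
    b = np.zeros(n)
    b[n - 1] = 1.0
    p = spsolve(sp.csc_matrix(A), b)
    return np.clip(p, 0.0, None)


def _telegraph_fsp(rates, d: float, N: int) -> np.ndarray:
    """Stationary distribution over states (g, n), n = 0..N, reflecting at n = N."""
    son, soff, rho = rates.sigma_on, rates.sigma_off, rates.rho
    idx = lambda g, n: 2 * n + g  # noqa: E731
    rows, cols, vals = [], [], []

    def add(i, j, rate):
        rows.append(i)
        cols.append(j)
        vals.append(rate)
        rows.append(j)
        cols.append(j)
        vals.append(-rate)

    for n in range(N + 1):
        add(idx(1, n), idx(0, n), son)
        add(idx(0, n), idx(1, n), soff)
        if n < N:
            add(idx(1, n + 1), idx(1, n), rho)
        if n > 0:
            add(idx(0, n - 1), idx(0, n), n * d)
            add(idx(1, n - 1), idx(1, n), n * d)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(2 * (N + 1), 2 * (N + 1)))
    p = _solve_stationary(A)
    return p[0::2] + p[1::2]  # marginal over promoter state


def telegraph_pmf(spec: MatureModelSpec, eps: float = 1e-8, min_truncation: int = 0) -> CountPMF:
    """Steady-state mature mRNA distribution of the telegraph model via FSP.

    The truncation starts at mean + 10*sqrt(variance) (closed-form moments)
    and is doubled until the mass near the boundary falls below ``eps``.
    ``min_truncation`` forces the support to reach at least that count
    (used when an observation lies beyond the adaptive truncation).
    """
    if not 0 < eps < 1:
        raise InvalidParameterError(f"eps must be in (0, 1), got {eps!r}")
    if min_truncation > TRUNCATION_CAP:
        raise TruncationError(TRUNCATION_CAP, float("nan"))
    r = spec.rates
    if r.rho == 0:
        return CountPMF([1.0], tail_mass_bound=0.0)
    if r.sigma_on == 0:
        # promoter can only leave ON; if it starts OFF it never produces.
        # Stationary state is the empty one unless sigma_off is also 0.
        if r.sigma_off > 0:
            return CountPMF([1.0], tail_mass_bound=0.0)
        raise UndefinedQuantityError("stationary state undefined for frozen promoter")
    mean, var = telegraph_moments(spec)
    N = max(8, min_truncation, int(np.ceil(mean + 10.0 * np.sqrt(var))))
    tail = float("nan")
    while True:
        if N > TRUNCATION_CAP:
            raise TruncationError(TRUNCATION_CAP, tail)
        p = _telegraph_fsp(r, spec.d, N)
        tail = float(p[max(0, N - 1):].sum())
        if tail < eps:
            break
        N *= 2
    return CountPMF(p, tail_mass_bound=tail)


def _count_window_pmf(rates, rate_on: float, tau: float, K: int, n_terms: int) -> np.ndarray:
    """P(#initiations in [0, tau], k = 0..K) for the telegraph-gated Poisson process.

    Uniformization on the augmented chain (promoter state, count), initialized
    at the stationary promoter occupancy.  Counts beyond K leak out, so the
    returned vector is substochastic by exactly the probability of exceeding K.
    """
    son, soff = rates.sigma_on, rates.sigma_off
    lam = son + soff + rate_on
    f_on = rates.fraction_on

    # state: p[g, k]; g = 0 OFF, 1 ON
    p = np.zeros((2, K + 1))
    p[0, 0] = 1.0 - f_on
    p[1, 0] = f_on

    a_on, a_off, a_rho = son / lam, soff / lam, rate_on / lam
    lt = lam * tau
    ns = np.arange(n_terms + 1)
    logw = ns * np.log(lt) - lt - gammaln(ns + 1) if lt > 0 else np.where(ns == 0, 0.0, -np.inf)
    w = np.exp(logw)

    res = w[0] * p
    for n in range(1, n_terms + 1):
        p0 = p[0] * (1.0 - a_on) + p[1] * a_off
        p1 = p[1] * (1.0 - a_off - a_rho) + p[0] * a_on
        p1[1:] += p[1, :-1] * a_rho  # initiation advances the count; k = K leaks
        p = np.stack((p0, p1))
        if w[n] > 0.0:
            res += w[n] * p
    return res[0] + res[1]


def delay_polII_pmf(spec: NascentModelSpec, eps: float = 1e-8, min_truncation: int = 0) -> CountPMF:
    """Steady-state distribution of the number of bound Pol II (delay telegraph model).

    Exact for fixed residence time tau: a Pol II is on the gene iff it
    initiated within the last tau, so k is the count of initiation events of
    the stationary ON/OFF-modulated Poisson process over a window of length
    tau.  The mean is rho * tau * fON.
    """
    if not 0 < eps < 1:
        raise InvalidParameterError(f"eps must be in (0, 1), got {eps!r}")
    r = spec.rates
    if r.rho == 0:
        return CountPMF([1.0], tail_mass_bound=0.0)
    if r.sigma_on == 0 and r.sigma_off > 0:
        return CountPMF([1.0], tail_mass_bound=0.0)
    if r.sigma_on + r.sigma_off == 0:
        raise UndefinedQuantityError("stationary promoter state undefined")

    if min_truncation > TRUNCATION_CAP:
        raise TruncationError(TRUNCATION_CAP, float("nan"))
    lam_max = r.rho * spec.tau  # always-ON Poisson upper envelope
    K = max(8, min_truncation, int(_poisson.isf(min(eps * 1e-2, 1e-10), lam_max)) + 2)
    deficit = float("nan")
    while True:
        if K > TRUNCATION_CAP:
            raise TruncationError(TRUNCATION_CAP, deficit)
        lt = (r.sigma_on + r.sigma_off + r.rho) * spec.tau
        n_terms = max(16, int(_poisson.isf(1e-13, lt)) + 1)
        p = _count_window_pmf(r, r.rho, spec.tau, K, n_terms)
        deficit = float(max(0.0, 1.0 - p.sum()))
        if deficit < eps:
            break
        K *= 2
    return CountPMF(p, tail_mass_bound=deficit)


@lru_cache(maxsize=32)
def _eulerian_rows(jmax: int) -> tuple[np.ndarray, ...]:
    """Row j: P(floor(U1+...+Uj) = r), r = 0..j-1 — Eulerian numbers / j!.

    Built by the all-positive recurrence
    E(j, r) = ((r+1) E(j-1, r) + (j-r) E(j-1, r-1)) / j, stable for any j.
    """
    rows = [np.array([1.0])]  # j = 1
    for j in range(2, jmax + 1):
        prev = rows[-1]
        r = np.arange(j)
        cur = np.zeros(j)
        cur[: j - 1] += (r[: j - 1] + 1) * prev
        cur[1:] += (j - r[1:]) * prev
        rows.append(cur / j)
    return tuple(rows)


def signal_conditional_bin_probs(k: int, geometry: GeneGeometry) -> np.ndarray:
    """Bin probabilities of the total signal given k bound Pol II.

    Bin i >= 1 is the event total signal in (i-1, i]; atoms at integer m
    (all-plateau configurations) fall in bin m.  Returns a vector over bins
    0..k.  k = 0 is the point mass at bin 0.
    """
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    if k == 0:
        return np.array([1.0])
    b = geometry.L2 / geometry.L  # plateau (atom at 1) weight per Pol II
    out = np.zeros(k + 1)
    weights = _binom.pmf(np.arange(k + 1), k, b)  # m = number of plateau Pol II
    rows = _eulerian_rows(k)
    for m in range(k + 1):
        j = k - m  # Pol II in the rising region: Irwin-Hall order j shifted by m
        if j == 0:
            out[m] += weights[m]
        else:
            # sum of j uniforms in (r, r+1] -> bin m + r + 1
            out[m + 1 : m + j + 1] += weights[m] * rows[j - 1]
    return out


_BIN_MATRIX_CACHE: dict[tuple[float, float], np.ndarray] = {}


def _bin_matrix(K: int, L1: float, L2: float) -> np.ndarray:
    """Rows k = 0..K of signal_conditional_bin_probs, padded to K+1 bins.

    Grown monotonically per geometry and cached, so repeated likelihood
    evaluations at different truncations reuse one table.
    """
    key = (L1, L2)
    cached = _BIN_MATRIX_CACHE.get(key)
    if cached is not None and cached.shape[0] > K:
        return cached[: K + 1, : K + 1]
    geom = GeneGeometry(L1, L2)
    B = np.zeros((K + 1, K + 1))
    for k in range(K + 1):
        B[k, : k + 1] = signal_conditional_bin_probs(k, geom)
    _BIN_MATRIX_CACHE[key] = B
    return B


def signal_bin_pmf(spec: NascentModelSpec, eps: float = 1e-8, min_truncation: int = 0) -> SignalBinPMF:
    """Distribution over integer fluorescence bins of the transcription-site signal.

    Mixture over the bound Pol II number k: S(i) = sum_k P(k) * P(bin i | k),
    with P(k) from :func:`delay_polII_pmf`.  Bin 0 is zero signal (k = 0).
    """
    pk = delay_polII_pmf(spec, eps=eps, min_truncation=min_truncation)
    B = _bin_matrix(pk.K, spec.geometry.L1, spec.geometry.L2)
    s = pk.probs @ B
    return SignalBinPMF(s, tail_mass_bound=pk.tail_mass_bound)


def signal_mean(spec: NascentModelSpec, eps: float = 1e-8) -> float:
    """Mean of the continuous (pre-binning) total signal: E[k] * (L1/2 + L2) / L."""
    return delay_polII_pmf(spec, eps=eps).mean() * spec.geometry.mean_signal_per_polII


def convolve_pmf(p, q):
    """Exact discrete convolution of two PMFs of the same kind.

    Models the total from two independent gene copies: the two-copy count
    (or binned-signal) distribution is the single-copy distribution convolved
    with itself.
    """
    if type(p) is not type(q):
        raise InvalidParameterError(
            f"cannot convolve {type(p).__name__} with {type(q).__name__}: "
            "mixed bin conventions"
        )
    out = np.convolve(p.probs, q.probs)
    return type(p)(out, tail_mass_bound=p.tail_mass_bound + q.tail_mass_bound)


def derived_quantities(params) -> dict:
    """Burst descriptors: fraction ON, burst size rho/sigma_off, effective rate rho*fON."""
    f_on = params.fraction_on  # raises if sigma_on + sigma_off == 0
    if params.sigma_off == 0:
        burst = np.inf
        infinite = True
    else:
        burst = params.rho / params.sigma_off
        infinite = False
    return {
        "fraction_on": f_on,
        "burst_size": burst,
        "burst_size_infinite": infinite,
        "effective_rate": params.rho * f_on,
    }


def fano_factor(pmf) -> float:
    """Variance over mean of a PMF; 1 for Poisson, 0 for a point mass."""
    m = pmf.mean()
    if m <= 0:
        raise UndefinedQuantityError("Fano factor undefined for zero-mean distribution")
    return pmf.variance() / m
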