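"""Stochastic simulation of telegraph / delay telegraph gene expression.

Mature mRNA counts come from Gillespie's stochastic simulation algorithm
(SSA) on the telegraph reactions; nascent-signal data come from a delayed
SSA in which each initiation event schedules its own departure a fixed
residence time tau later.  Because removal is deterministic, the gene-bound
Pol II at sampling time are exactly the initiations of the last tau minutes;
with the promoter started from its stationary occupancy the modulated
initiation process is stationary from time zero, so nascent snapshots need
no burn-in.  Mature counts are burnt in for
max(10/d, 10/(sigma_on + sigma_off)) minutes.

A Pol II initiated at time t_i has, at sampling time t, normalized position
x = (t - t_i)/tau and contributes the trapezoidal signal
q(x) = x*L/L1 for x <= L1/L else 1.  The per-cell total signal is the sum
over bound Pol II and is discretized by ceiling, so a total in (i-1, i]
lands in integer bin i and an exactly-zero signal in bin 0 — the same bin
convention the inference likelihood integrates over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ._exceptions import InvalidParameterError
from .types import MatureModelSpec, NascentModelSpec, RateParams

__all__ = [
    "SimConfig",
    "NascentSample",
    "simulate_mature_cells",
    "simulate_nascent_cells",
    "perturb_initiation_rates",
    "simulate_two_copy_cells",
    "simulate_intensity_trace",
    "simulate_dna_content",
    "simulate_cell_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Number of cells, RNG seed, and optional burn-in override (minutes)."""

    n_cells: int
    seed: int = 0
    burn_in: float | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")


@dataclass
class NascentSample:
    """Per-cell delayed-SSA output: Pol II counts, positions, continuous and binned signal."""

    counts: np.ndarray  # J_n, bound Pol II per cell
    positions: np.ndarray  # flat normalized positions in [0, 1]
    offsets: np.ndarray  # cell n owns positions[offsets[n]:offsets[n+1]]
    signal: np.ndarray  # continuous total signal q_n per cell
    bins: np.ndarray  # ceil(q_n); 0 iff q_n == 0

    def positions_of(self, n: int) -> np.ndarray:
        return self.positions[self.offsets[n]: self.offsets[n + 1]]


def _check_rates(rates: RateParams, need_stationary: bool = True):
    if need_stationary and rates.sigma_on + rates.sigma_off == 0:
        raise InvalidParameterError(
            "sigma_on + sigma_off must be > 0 for stationary initialization"
        )


@njit(cache=True)
def _ssa_mature_kernel(sigma_on, sigma_off, rho_per_cell, d, t_end, seed):
    np.random.seed(seed)
    n_cells = rho_per_cell.size
    out = np.empty(n_cells, np.int64)
    f_on = sigma_on / (sigma_on + sigma_off)
    for c in range(n_cells):
        rho = rho_per_cell[c]
        g = 1 if np.random.random() < f_on else 0
        n = 0
        t = 0.0
        while True:
            r_switch = sigma_on if g == 0 else sigma_off
            r_prod = rho if g == 1 else 0.0
            r_deg = n * d
            tot = r_switch + r_prod + r_deg
            if tot <= 0.0:
                break
            t -= math.log(np.random.random()) / tot
            if t > t_end:
                break
            u = np.random.random() * tot
            if u < r_switch:
                g = 1 - g
            elif u < r_switch + r_prod:
                n += 1
            else:
                n -= 1
        out[c] = n
    return out


def simulate_mature_cells(
    spec: MatureModelSpec,
    cfg: SimConfig,
    rho_per_cell: np.ndarray | None = None,
) -> np.ndarray:
    """One stationary mature mRNA count per cell from the telegraph SSA.

    ``rho_per_cell`` optionally supplies a per-cell initiation rate (external
    noise: each cell keeps one rho' for its whole history).
    """
    r = spec.rates
    if rho_per_cell is None:
        rho_per_cell = np.full(cfg.n_cells, r.rho, dtype=float)
    else:
        rho_per_cell = np.asarray(rho_per_cell, dtype=float)
        if rho_per_cell.size != cfg.n_cells:
            raise InvalidParameterError("rho_per_cell length must equal n_cells")
        if np.any(rho_per_cell < 0):
            raise InvalidParameterError("per-cell initiation rates must be >= 0")
    if np.all(rho_per_cell == 0):
        return np.zeros(cfg.n_cells, dtype=np.int64)
    _check_rates(r)
    burn = cfg.burn_in
    if burn is None:
        burn = max(10.0 / spec.d, 10.0 / (r.sigma_on + r.sigma_off))
    return _ssa_mature_kernel(
        r.sigma_on, r.sigma_off, rho_per_cell, spec.d, burn, cfg.seed % 2**31
    )


@njit(cache=True)
def _ssa_nascent_kernel(sigma_on, sigma_off, rho, tau, n_cells, seed):
    """Initiation times over a stationary window [0, tau] for each cell.

    Returns (counts, flat initiation-age fractions x = (tau - t_i)/tau).
    """
    np.random.seed(seed)
    f_on = sigma_on / (sigma_on + sigma_off)
    counts = np.empty(n_cells, np.int64)
    cap = 1024
    flat = np.empty(cap, np.float64)
    total = 0
    for c in range(n_cells):
        g = 1 if np.random.random() < f_on else 0
        t = 0.0
        k = 0
        while True:
            r_switch = sigma_on if g == 0 else sigma_off
            r_init = rho if g == 1 else 0.0
            tot = r_switch + r_init
            if tot <= 0.0:
                break
            t -= math.log(np.random.random()) / tot
            if t > tau:
                break
            if np.random.random() * tot < r_switch:
                g = 1 - g
            else:
                if total >= cap:
                    cap *= 2
                    grown = np.empty(cap, np.float64)
                    grown[:total] = flat[:total]
                    flat = grown
                flat[total] = (tau - t) / tau
                total += 1
                k += 1
        counts[c] = k
    return counts, flat[:total]


def _trapezoid_signal(x: np.ndarray, linear_fraction: float) -> np.ndarray:
    return np.minimum(x / linear_fraction, 1.0)


def simulate_nascent_cells(spec: NascentModelSpec, cfg: SimConfig) -> NascentSample:
    """Delayed-SSA snapshot of bound Pol II per cell with trapezoidal signals."""
    r = spec.rates
    if r.rho == 0:
        z = np.zeros(cfg.n_cells, dtype=np.int64)
        return NascentSample(
            counts=z,
            positions=np.empty(0),
            offsets=np.zeros(cfg.n_cells + 1, dtype=np.int64),
            signal=np.zeros(cfg.n_cells),
            bins=z.copy(),
        )
    _check_rates(r)
    counts, positions = _ssa_nascent_kernel(
        r.sigma_on, r.sigma_off, r.rho, spec.tau, cfg.n_cells, cfg.seed % 2**31
    )
    offsets = np.zeros(cfg.n_cells + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    q = _trapezoid_signal(positions, spec.geometry.linear_fraction)
    signal = np.zeros(cfg.n_cells)
    nonzero = counts > 0
    if positions.size:
        # starts of non-empty segments are strictly increasing, so reduceat
        # sums each one exactly up to the next non-empty start / array end.
        signal[nonzero] = np.add.reduceat(q, offsets[:-1][nonzero], dtype=float)
    bins = np.ceil(signal - 1e-12).astype(np.int64)
    bins[signal == 0.0] = 0
    return NascentSample(counts=counts, positions=positions, offsets=offsets,
                         signal=signal, bins=bins)


def perturb_initiation_rates(rho: float, cv: float, n_cells: int, seed: int) -> np.ndarray:
    """Per-cell log-normal initiation rates with arithmetic mean rho and SD cv*rho."""
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    if rho < 0:
        raise InvalidParameterError("rho must be >= 0")
    if cv == 0 or rho == 0:
        return np.full(n_cells, float(rho))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(rho) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_cells)


def simulate_two_copy_cells(spec, cfg: SimConfig, mode: str = "independent") -> np.ndarray:
    """Per-cell totals for two gene copies.

    ``independent``: sum of two independent single-copy simulations.
    ``synchronized``: one shared promoter trajectory initiating at 2*rho.
    Mature specs yield summed counts; nascent specs yield summed integer bins
    (matching the convolution convention of the two-copy model PMF).
    """
    if mode not in ("independent", "synchronized"):
        raise InvalidParameterError(f"unknown two-copy mode {mode!r}")

    def one(s, cfg_):
        if isinstance(s, MatureModelSpec):
            return simulate_mature_cells(s, cfg_)
        return simulate_nascent_cells(s, cfg_).bins

    if mode == "independent":
        a = one(spec, cfg)
        b = one(spec, SimConfig(cfg.n_cells, seed=cfg.seed + 1_000_003, burn_in=cfg.burn_in))
        return a + b
    doubled = RateParams(spec.rates.sigma_on, spec.rates.sigma_off, 2.0 * spec.rates.rho)
    if isinstance(spec, MatureModelSpec):
        return one(MatureModelSpec(doubled, spec.d), cfg)
    return one(NascentModelSpec(doubled, spec.tau, spec.geometry), cfg)


@njit(cache=True)
def _promoter_initiations_kernel(sigma_on, sigma_off, rho, t_end, seed):
    """All initiation times of the modulated Poisson process on [0, t_end]."""
    np.random.seed(seed)
    f_on = sigma_on / (sigma_on + sigma_off)
    g = 1 if np.random.random() < f_on else 0
    cap = 1024
    times = np.empty(cap, np.float64)
    n = 0
    t = 0.0
    while True:
        r_switch = sigma_on if g == 0 else sigma_off
        r_init = rho if g == 1 else 0.0
        tot = r_switch + r_init
        if tot <= 0.0:
            break
        t -= math.log(np.random.random()) / tot
        if t > t_end:
            break
        if np.random.random() * tot < r_switch:
            g = 1 - g
        else:
            if n >= cap:
                cap *= 2
                grown = np.empty(cap, np.float64)
                grown[:n] = times[:n]
                times = grown
            times[n] = t
            n += 1
    return times[:n]


def simulate_intensity_trace(
    spec: NascentModelSpec,
    duration: float,
    dt: float,
    seed: int,
    burn_in: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous transcription-site intensity sampled on a regular time grid.

    Returns (times, signal).  The promoter starts from stationary occupancy
    and the first tau minutes are discarded so every sample sees a full
    residence window.  Mimics a live-cell trace of the same reporter.
    """
    if not duration > dt > 0:
        raise InvalidParameterError("need duration > dt > 0")
    r = spec.rates
    n_samples = int(round(duration / dt)) + 1
    times = np.arange(n_samples) * dt
    if r.rho == 0:
        return times, np.zeros(n_samples)
    _check_rates(r)
    burn = spec.tau if burn_in is None else burn_in
    t_end = burn + duration
    init = _promoter_initiations_kernel(
        r.sigma_on, r.sigma_off, r.rho, t_end, seed % 2**31
    )
    af = spec.geometry.linear_fraction
    signal = np.empty(n_samples)
    sample_t = burn + times
    lo = np.searchsorted(init, sample_t - spec.tau, side="left")
    hi = np.searchsorted(init, sample_t, side="right")
    for j in range(n_samples):
        x = (sample_t[j] - init[lo[j]: hi[j]]) / spec.tau
        signal[j] = np.minimum(x / af, 1.0).sum()
    return times, signal


def simulate_cell_table(
    rates: RateParams,
    n_g1: int,
    n_g2: int,
    d: float = 1.0,
    tau: float = 0.5,
    geometry=None,
    dna_means: tuple[float, float] = (100.0, 200.0),
    dna_sds: tuple[float, float] = (10.0, 20.0),
    intensity_unit: float = 100.0,
    seed: int = 0,
):
    """Full synthetic cell table in the preprocess CSV schema.

    G1 cells carry one gene copy, G2 cells two independent copies.  Spot
    counts come from the mature-mRNA SSA plus one transcription-site spot
    whenever nascent signal is present; the brightest nuclear intensity is
    the nascent signal times ``intensity_unit`` (the single-mRNA intensity,
    which is also every cell's cytoplasmic median); DNA-stain intensities
    come from the two-Gaussian mixture.  Phases are left "unassigned" so the
    classifier can be exercised end to end.
    """
    import pandas as pd

    from .types import GeneGeometry as _GG

    geom = geometry or _GG(862.0, 2200.0)
    n = n_g1 + n_g2
    mspec = MatureModelSpec(rates, d)
    nspec = NascentModelSpec(rates, tau, geom)
    mature_g1 = simulate_mature_cells(mspec, SimConfig(max(n_g1, 1), seed=seed))[:n_g1]
    mature_g2 = simulate_two_copy_cells(mspec, SimConfig(max(n_g2, 1), seed=seed + 1))[:n_g2]
    sig_g1 = simulate_nascent_cells(nspec, SimConfig(max(n_g1, 1), seed=seed + 2)).signal[:n_g1]
    s2a = simulate_nascent_cells(nspec, SimConfig(max(n_g2, 1), seed=seed + 3)).signal[:n_g2]
    s2b = simulate_nascent_cells(nspec, SimConfig(max(n_g2, 1), seed=seed + 4)).signal[:n_g2]
    dna, _ = simulate_dna_content(n_g1, n_g2, dna_means, dna_sds, seed=seed + 5)
    spot = np.concatenate([mature_g1, mature_g2]).astype(np.int64)
    signal = np.concatenate([sig_g1, s2a + s2b])
    spot = spot + (signal > 0)  # the transcription site counts as one spot
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(n)],
            "spot_count": spot,
            "brightest_nuclear_intensity": signal * intensity_unit,
            "median_cytoplasmic_intensity": np.full(n, float(intensity_unit)),
            "integrated_dna_intensity": dna,
            "phase": ["unassigned"] * n,
        }
    )


def simulate_dna_content(
    n_g1: int,
    n_g2: int,
    means: tuple[float, float],
    sds: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic integrated DNA-stain intensities from a two-component Gaussian mixture.

    Returns (intensities, true_labels) with labels "G1"/"G2".  Fixture for
    the cell-cycle classifier; emulates the bimodal integrated nuclear
    DNA-stain (DAPI) intensity of an asynchronous population.
    """
    m1, m2 = means
    s1, s2 = sds
    if m1 <= 0 or m2 <= 0 or s1 <= 0 or s2 <= 0:
        raise InvalidParameterError("means and sds must be positive")
    if m2 <= m1:
        raise InvalidParameterError("G2 mean must exceed G1 mean")
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(m1, s1, n_g1), rng.normal(m2, s2, n_g2)])
    labels = np.array(["G1"] * n_g1 + ["G2"] * n_g2)
    return x, labels
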