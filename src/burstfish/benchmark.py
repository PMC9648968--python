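"""Synthetic accuracy study: paired mature/nascent inference over a parameter grid.

For every ground-truth parameter set on an equidistant grid (filtered by the
effective-transcription-rate constraint rho * fON < threshold), synthetic
mature counts and nascent signal bins are simulated, both models are fitted,
and per-parameter relative errors plus the mean relative error (MRE)

    MRE = (1/M) sum_i |theta_i* - theta_true,i| / |theta_true,i|

are recorded.  Optional per-cell log-normal perturbation of the initiation
rate (external noise) applies to the mature pipeline only, emulating
post-transcriptional noise sources absent from nascent data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._exceptions import InvalidParameterError
from .inference import (
    MatureScale,
    NascentScale,
    ObservedDataset,
    OptimizerConfig,
    SearchSpace,
    fit,
)
from .simulator import SimConfig, perturb_initiation_rates, simulate_mature_cells, simulate_nascent_cells
from .types import MatureModelSpec, NascentModelSpec, RateParams

__all__ = [
    "GridSpec",
    "BenchmarkRecord",
    "generate_parameter_grid",
    "stratified_fon_sample",
    "relative_errors",
    "run_benchmark",
    "binned_median_relative_error",
]


@dataclass(frozen=True)
class GridSpec:
    """Equidistant grid over (sigma_on, sigma_off, rho) with an effective-rate filter.

    Points in each dimension sit at range * j / m for j = 1..m (zero excluded,
    upper endpoint included).  A parameter set survives only if
    rho * sigma_on / (sigma_on + sigma_off) < threshold (strict).
    """

    sigma_on_max: float = 150.0
    sigma_off_max: float = 150.0
    rho_max: float = 250.0
    points_per_dim: int = 10
    threshold: float = 100.0

    def __post_init__(self):
        if self.points_per_dim < 2:
            raise InvalidParameterError("points_per_dim must be >= 2")
        if self.threshold <= 0:
            raise InvalidParameterError("threshold must be > 0")


def generate_parameter_grid(spec: GridSpec) -> list[RateParams]:
    """Cartesian grid filtered by the effective transcription-rate constraint."""
    m = spec.points_per_dim
    axis = lambda top: top * np.arange(1, m + 1) / m  # noqa: E731
    out = []
    for son in axis(spec.sigma_on_max):
        for soff in axis(spec.sigma_off_max):
            for rho in axis(spec.rho_max):
                if rho * son / (son + soff) < spec.threshold:
                    out.append(RateParams(son, soff, rho))
    if not out:
        raise InvalidParameterError("no parameter set survives the effective-rate constraint")
    return out


def stratified_fon_sample(grid: list[RateParams], n: int, seed: int = 0) -> list[RateParams]:
    """Systematic subsample of a grid stratified by fraction ON.

    Sorting by fON and taking every len/n-th point (random seeded phase)
    preserves the fON composition of the full grid, which dominates the
    between-subsample variance of accuracy comparisons.
    """
    if n >= len(grid):
        return list(grid)
    order = sorted(grid, key=lambda p: (p.fraction_on, p.rho, p.sigma_on))
    u = np.random.default_rng(seed).random()
    idx = np.floor((np.arange(n) + u) * len(order) / n).astype(int)
    return [order[i] for i in idx]


def relative_errors(theta_star: RateParams, theta_true: RateParams) -> dict:
    """Per-parameter relative errors |theta* - theta| / |theta| and their mean (MRE)."""
    errs = {}
    for name in ("sigma_on", "sigma_off", "rho"):
        true = getattr(theta_true, name)
        if true == 0:
            raise InvalidParameterError(f"true {name} is zero; relative error undefined")
        errs[name] = abs(getattr(theta_star, name) - true) / abs(true)
    errs["mre"] = float(np.mean([errs[n] for n in ("sigma_on", "sigma_off", "rho")]))
    return errs


@dataclass
class BenchmarkRecord:
    theta_true: RateParams
    fon_true: float
    errors_mature: dict
    errors_nascent: dict
    fit_mature: dict = field(default_factory=dict)
    fit_nascent: dict = field(default_factory=dict)

    @property
    def mre_mature(self) -> float:
        return self.errors_mature["mre"]

    @property
    def mre_nascent(self) -> float:
        return self.errors_nascent["mre"]

    def to_dict(self) -> dict:
        return {
            "sigma_on": self.theta_true.sigma_on,
            "sigma_off": self.theta_true.sigma_off,
            "rho": self.theta_true.rho,
            "fon_true": self.fon_true,
            "errors_mature": self.errors_mature,
            "errors_nascent": self.errors_nascent,
            "fit_mature": self.fit_mature,
            "fit_nascent": self.fit_nascent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkRecord":
        return cls(
            theta_true=RateParams(d["sigma_on"], d["sigma_off"], d["rho"]),
            fon_true=d["fon_true"],
            errors_mature=d["errors_mature"],
            errors_nascent=d["errors_nascent"],
            fit_mature=d.get("fit_mature", {}),
            fit_nascent=d.get("fit_nascent", {}),
        )


def _fit_one(values, kind, scale, seed, space, optimizer):
    data = ObservedDataset(kind=kind, values=values)
    cfg = optimizer or OptimizerConfig()
    cfg = OptimizerConfig(
        popsize=cfg.popsize, maxiter=cfg.maxiter, tol=cfg.tol, seed=seed,
        restarts=cfg.restarts, polish=cfg.polish, eps=cfg.eps,
    )
    return fit(data, scale, space=space, optimizer=cfg)


def run_benchmark(
    grid: list[RateParams],
    n_cells: int = 10_000,
    noise_cv: float = 0.0,
    seed_base: int = 0,
    d: float = 1.0,
    tau: float = 0.5,
    geometry=None,
    space: SearchSpace | None = None,
    optimizer: OptimizerConfig | None = None,
    checkpoint: str | Path | None = None,
) -> list[BenchmarkRecord]:
    """Simulate and fit mature + nascent data for every grid point.

    ``noise_cv`` > 0 draws one log-normal initiation rate per cell (mean rho,
    SD noise_cv * rho) for the mature simulation only; the nascent pipeline is
    byte-identical across noise settings given the same seeds.  With a
    ``checkpoint`` path (JSON lines) completed points are skipped on re-run;
    individual fit failures are recorded, not fatal.
    """
    nascent_scale = NascentScale(tau=tau) if geometry is None else NascentScale(tau, geometry)
    mature_scale = MatureScale(d=d)
    done: dict[int, BenchmarkRecord] = {}
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt and ckpt.exists():
        for line in ckpt.read_text().splitlines():
            obj = json.loads(line)
            done[obj["index"]] = BenchmarkRecord.from_dict(obj["record"])
    records = []
    for i, theta in enumerate(grid):
        if i in done:
            records.append(done[i])
            continue
        seed = seed_base + 1000 * i
        try:
            rho_cells = (
                perturb_initiation_rates(theta.rho, noise_cv, n_cells, seed + 1)
                if noise_cv > 0
                else None
            )
            mature = simulate_mature_cells(
                MatureModelSpec(theta, d), SimConfig(n_cells, seed=seed), rho_per_cell=rho_cells
            )
            nascent = simulate_nascent_cells(
                NascentModelSpec(theta, tau, nascent_scale.geometry),
                SimConfig(n_cells, seed=seed + 2),
            )
            fm = _fit_one(mature, "mature", mature_scale, seed + 3, space, optimizer)
            fn = _fit_one(nascent.bins, "nascent", nascent_scale, seed + 4, space, optimizer)
            rec = BenchmarkRecord(
                theta_true=theta,
                fon_true=theta.fraction_on,
                errors_mature=relative_errors(fm.theta_star, theta),
                errors_nascent=relative_errors(fn.theta_star, theta),
                fit_mature=fm.to_dict(),
                fit_nascent=fn.to_dict(),
            )
        except Exception as exc:  # record, don't abort the sweep
            rec = BenchmarkRecord(
                theta_true=theta,
                fon_true=theta.fraction_on,
                errors_mature={"error": str(exc), "mre": float("nan")},
                errors_nascent={"error": str(exc), "mre": float("nan")},
            )
        records.append(rec)
        if ckpt:
            with ckpt.open("a") as fh:
                fh.write(json.dumps({"index": i, "record": rec.to_dict()}) + "\n")
    return records


def binned_median_relative_error(
    records: list[BenchmarkRecord],
    bin_centers=tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
    which: str = "nascent",
    half_width: float = 0.05,
) -> dict:
    """Median relative error per parameter within fON windows [x - h, x + h].

    Parameters summarized: sigma_on, sigma_off, rho, plus the derived burst
    size rho/sigma_off and the estimated fraction ON (absolute error for the
    latter two computed from the stored fits).  Empty windows yield NaN.
    """
    if not records:
        raise InvalidParameterError("records must be non-empty")
    key = f"errors_{which}"
    fit_key = f"fit_{which}"
    out = {c: {} for c in bin_centers}
    for c in bin_centers:
        sel = [r for r in records if abs(r.fon_true - c) <= half_width]
        for name in ("sigma_on", "sigma_off", "rho"):
            vals = [getattr(r, key)[name] for r in sel if name in getattr(r, key)]
            out[c][name] = float(np.median(vals)) if vals else float("nan")
        bs, fo = [], []
        for r in sel:
            f = getattr(r, fit_key)
            if not f or "derived" in f and f["derived"].get("burst_size") is None:
                continue
            true_bs = r.theta_true.rho / r.theta_true.sigma_off
            bs.append(abs(f["derived"]["burst_size"] - true_bs) / true_bs)
            fo.append(abs(f["derived"]["fraction_on"] - r.fon_true) / r.fon_true)
        out[c]["burst_size"] = float(np.median(bs)) if bs else float("nan")
        out[c]["fraction_on"] = float(np.median(fo)) if fo else float("nan")
    return out
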