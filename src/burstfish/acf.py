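"""Normalized autocorrelation functions of transcription-site intensity traces.

Live-cell traces show cell-to-cell variation in overall fluorescence gain,
so kinetics are compared through per-trace normalized ACFs: each trace is
mean-subtracted, its autocovariance divided by its own variance (lag 0 = 1),
and curves are averaged across traces.  The ACF is therefore invariant to
any affine transformation (gain and offset) of a trace.  A model ACF is
scored against a reference curve by the sum of squared deviations over the
model's lags, with the reference linearly interpolated onto those lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._exceptions import InvalidParameterError
from .simulator import simulate_intensity_trace
from .types import NascentModelSpec

__all__ = ["ACFCurve", "normalized_acf", "acf_ssr", "simulate_population_acf"]


@dataclass(frozen=True)
class ACFCurve:
    """Averaged per-trace normalized autocorrelation: value 1 at lag 0."""

    lags: np.ndarray  # minutes, strictly increasing from 0
    values: np.ndarray
    n_traces: int

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if lags.size != vals.size or lags.size == 0:
            raise InvalidParameterError("lags and values must have equal, nonzero length")
        if lags[0] != 0 or np.any(np.diff(lags) <= 0):
            raise InvalidParameterError("lags must increase strictly from 0")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)


def _single_acf(x: np.ndarray, n_lags: int, biased: bool) -> np.ndarray | None:
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float((x @ x) / n)
    if var <= 0:
        return None
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: n_lags + 1] / n
    if not biased:
        acov *= n / (n - np.arange(n_lags + 1))
    return acov / acov[0]


def normalized_acf(traces, max_lag: float, dt: float, biased: bool = True) -> ACFCurve:
    """Average per-trace normalized ACF up to ``max_lag`` (minutes).

    ``traces`` share the sampling interval ``dt``; each must be longer than
    2 * max_lag / dt samples.  Zero-variance traces are excluded with a
    warning.  The biased autocovariance estimator (divide by N) is the
    default for variance stability at large lags; ``biased=False`` switches
    to the unbiased (divide by N - lag) form.
    """
    n_lags = int(round(max_lag / dt))
    if n_lags < 1:
        raise InvalidParameterError("max_lag must span at least one sampling interval")
    curves = []
    skipped = 0
    for x in traces:
        if len(x) <= 2 * n_lags:
            raise InvalidParameterError(
                f"trace length {len(x)} too short for max_lag {max_lag} at dt {dt}"
            )
        acf = _single_acf(np.asarray(x), n_lags, biased)
        if acf is None:
            skipped += 1
        else:
            curves.append(acf)
    if skipped:
        warnings.warn(f"excluded {skipped} zero-variance trace(s)", UserWarning, stacklevel=2)
    if not curves:
        raise InvalidParameterError("all traces had zero variance")
    values = np.mean(curves, axis=0)
    values[0] = 1.0
    return ACFCurve(lags=np.arange(n_lags + 1) * dt, values=values, n_traces=len(curves))


def acf_ssr(model: ACFCurve, reference: ACFCurve) -> float:
    """Sum of squared deviations between two ACF curves over the model's lags."""
    if model.lags[-1] > reference.lags[-1] or model.lags[0] < reference.lags[0]:
        raise InvalidParameterError(
            "model lags extend beyond the reference curve; cannot interpolate"
        )
    ref = np.interp(model.lags, reference.lags, reference.values)
    return float(((model.values - ref) ** 2).sum())


def simulate_population_acf(
    specs: list[NascentModelSpec],
    fractions,
    n_traces: int,
    duration: float,
    dt: float,
    max_lag: float,
    seed: int = 0,
) -> ACFCurve:
    """ACF of a population mixing traces from several parameter sets.

    ``fractions`` gives the proportion of traces simulated from each spec
    (e.g. cell-cycle composition G1/G2); counts are rounded, keeping the
    total at ``n_traces``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(specs) != fractions.size or fractions.size == 0:
        raise InvalidParameterError("specs and fractions must have equal, nonzero length")
    if np.any(fractions < 0) or fractions.sum() <= 0:
        raise InvalidParameterError("fractions must be non-negative and sum > 0")
    fractions = fractions / fractions.sum()
    counts = np.floor(fractions * n_traces).astype(int)
    counts[0] += n_traces - counts.sum()
    traces = []
    k = 0
    for spec, c in zip(specs, counts):
        for _ in range(c):
            _, sig = simulate_intensity_trace(spec, duration, dt, seed=seed + k)
            traces.append(sig)
            k += 1
    return normalized_acf(traces, max_lag=max_lag, dt=dt)
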