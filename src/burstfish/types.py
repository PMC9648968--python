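"""Core value types: kinetic parameters, model specifications and truncated PMFs.

The two-state (telegraph) promoter switches ON at rate ``sigma_on`` and OFF at
rate ``sigma_off``; transcripts initiate at rate ``rho`` while the promoter is
ON.  Mature transcripts decay at rate ``d`` (first-order); nascent transcripts
instead reside on the gene for a fixed elongation time ``tau`` and then leave.
All rates are per minute.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import InvalidParameterError, UndefinedQuantityError

__all__ = [
    "RateParams",
    "MatureModelSpec",
    "GeneGeometry",
    "NascentModelSpec",
    "CountPMF",
    "SignalBinPMF",
    "DEFAULT_GEOMETRY",
]


@dataclass(frozen=True)
class RateParams:
    """Promoter switching rates and initiation rate, in 1/min."""

    sigma_on: float
    sigma_off: float
    rho: float

    def __post_init__(self):
        for name in ("sigma_on", "sigma_off", "rho"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def fraction_on(self) -> float:
        """Stationary probability of the ON state, sigma_on / (sigma_on + sigma_off)."""
        s = self.sigma_on + self.sigma_off
        if s == 0:
            raise UndefinedQuantityError("fraction ON undefined when sigma_on + sigma_off = 0")
        return self.sigma_on / s

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_on, self.sigma_off, self.rho], dtype=float)


@dataclass(frozen=True)
class MatureModelSpec:
    """Telegraph model for mature mRNA: rates plus degradation rate ``d`` (1/min)."""

    rates: RateParams
    d: float = 1.0

    def __post_init__(self):
        if not math.isfinite(self.d) or self.d <= 0:
            raise InvalidParameterError(f"degradation rate d must be > 0, got {self.d!r}")


@dataclass(frozen=True)
class GeneGeometry:
    """Probe-region / gene-body lengths defining the trapezoidal signal profile.

    A polymerase at normalized position x on the gene emits signal
    q(x) = x * L / L1 while transcribing the 5' probe-binding region
    (x <= L1/L) and q(x) = 1 afterwards.
    """

    L1: float
    L2: float

    def __post_init__(self):
        if self.L1 <= 0:
            raise InvalidParameterError("L1 must be > 0")
        if self.L2 < 0:
            raise InvalidParameterError("L2 must be >= 0")

    @property
    def L(self) -> float:
        return self.L1 + self.L2

    @property
    def linear_fraction(self) -> float:
        """L1 / L: probability a uniformly placed Pol II sits in the rising region."""
        return self.L1 / self.L

    @property
    def mean_signal_per_polII(self) -> float:
        """Mean per-polymerase signal under the uniform-position assumption, (L1/2 + L2)/L."""
        return (self.L1 / 2.0 + self.L2) / self.L


#: PP7-tagged GAL10 reporter geometry (bp): 14x PP7 loop region then gene body.
DEFAULT_GEOMETRY = GeneGeometry(L1=862.0, L2=2200.0)


@dataclass(frozen=True)
class NascentModelSpec:
    """Delay telegraph model for nascent mRNA: rates, residence time ``tau`` (min), geometry."""

    rates: RateParams
    tau: float = 0.5
    geometry: GeneGeometry = DEFAULT_GEOMETRY

    def __post_init__(self):
        if not math.isfinite(self.tau) or self.tau <= 0:
            raise InvalidParameterError(f"elongation time tau must be > 0, got {self.tau!r}")


class _BasePMF:
    """Truncated probability vector over non-negative integers."""

    def __init__(self, probs, tail_mass_bound: float = 0.0):
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise InvalidParameterError("probability vector must be 1-D and non-empty")
        if np.any(p < -1e-12) or not np.all(np.isfinite(p)):
            raise InvalidParameterError("probabilities must be finite and non-negative")
        self.probs = np.clip(p, 0.0, None)
        self.tail_mass_bound = float(tail_mass_bound)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    @property
    def K(self) -> int:
        return self.probs.size - 1

    def mean(self) -> float:
        return float(self.support @ self.probs) / float(self.probs.sum())

    def variance(self) -> float:
        w = self.probs / self.probs.sum()
        m = float(self.support @ w)
        return float(((self.support - m) ** 2) @ w)

    def __len__(self) -> int:
        return self.probs.size

    def __getitem__(self, i):
        return self.probs[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.support, "probability": self.probs})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None, **meta):
        """JSON envelope with probabilities, truncation and tail-mass bound."""
        payload = {
            "kind": type(self).__name__,
            "truncation": self.K,
            "tail_mass_bound": self.tail_mass_bound,
            "probs": self.probs.tolist(),
            **meta,
        }
        if path is None:
            return json.dumps(payload)
        Path(path).write_text(json.dumps(payload))
        return None


class CountPMF(_BasePMF):
    """Distribution of a molecule count: mature mRNA number n or bound Pol II number k."""


class SignalBinPMF(_BasePMF):
    """Distribution over integer fluorescence bins.

    Bin 0 is the zero-signal bin (no bound Pol II); bin i >= 1 collects
    continuous signal in (i-1, i], with atoms at integer values assigned to
    their own-numbered bin.
    """
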