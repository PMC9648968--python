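"""Turn per-cell spot tables into inference-ready datasets.

A cell table is a CSV with one row per cell:

    cell_id, spot_count, brightest_nuclear_intensity,
    median_cytoplasmic_intensity, integrated_dna_intensity, phase

``spot_count`` is the total number of detected mRNA spots (nuclear +
cytoplasmic); the brightest nuclear spot is taken to be the transcription
site.  ``integrated_dna_intensity`` is the summed DNA-stain (e.g. DAPI)
signal over the nucleus mask and is bimodal over an asynchronous
population: the first mode is G1 (1x DNA content), the second G2 (2x).
``phase`` may be pre-assigned or left as "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._exceptions import InvalidParameterError, SchemaError

__all__ = [
    "COLUMNS",
    "CellCycleFit",
    "classify_cell_cycle",
    "normalize_transcription_site",
    "assemble_mature_counts",
    "load_cell_table",
    "write_cell_table",
]

COLUMNS = [
    "cell_id",
    "spot_count",
    "brightest_nuclear_intensity",
    "median_cytoplasmic_intensity",
    "integrated_dna_intensity",
    "phase",
]

_PHASES = {"G1", "G2", "undetermined", "unassigned"}


@dataclass(frozen=True)
class CellCycleFit:
    """Two-component Gaussian fit of DNA-content intensities (G1 then G2)."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    converged: bool

    @property
    def windows(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Classification windows mean +/- sd per component."""
        return (
            (self.means[0] - self.sds[0], self.means[0] + self.sds[0]),
            (self.means[1] - self.sds[1], self.means[1] + self.sds[1]),
        )


def classify_cell_cycle(
    intensities,
    min_cells: int = 50,
    window_sds: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, CellCycleFit]:
    """Label cells G1/G2/undetermined from integrated DNA-stain intensity.

    Fits a two-component Gaussian mixture by EM (initialized at the 25th and
    75th intensity percentiles) and labels a cell G1 (G2) when its intensity
    lies within one standard deviation of the first (second) component mean.
    Cells in neither window — or in both, when the windows overlap — are
    labeled undetermined.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.size < min_cells:
        raise InvalidParameterError(f"need at least {min_cells} cells, got {x.size}")
    init = np.percentile(x, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        means_init=init,
        tol=tol,
        max_iter=max_iter,
        n_init=1,
        random_state=0,
    )
    gm.fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge within {max_iter} iterations (tol {tol:g}); "
            f"lower bound {gm.lower_bound_:.6g}"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)  # G1 = lower DNA content
    means, sds = means[order], sds[order]
    weights = gm.weights_.ravel()[order]
    fit_ = CellCycleFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        converged=True,
    )
    sep = abs(means[1] - means[0])
    if sep < 0.5 * (sds[0] + sds[1]):
        warnings.warn(
            "DNA-content fit looks unimodal (component means closer than half "
            "the pooled SD); labeling all cells undetermined",
            UserWarning,
            stacklevel=2,
        )
        return np.full(x.size, "undetermined", dtype=object), fit_
    in_g1 = np.abs(x - means[0]) <= window_sds * sds[0]
    in_g2 = np.abs(x - means[1]) <= window_sds * sds[1]
    labels = np.full(x.size, "undetermined", dtype=object)
    labels[in_g1 & ~in_g2] = "G1"
    labels[in_g2 & ~in_g1] = "G2"
    # cells satisfying both windows stay undetermined (tie rule)
    return labels, fit_


def normalize_transcription_site(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Normalize brightest-nuclear-spot intensities by the cytoplasmic median.

    The normalizer is the dataset-wide median of the per-cell cytoplasmic
    median intensities (the single-mRNA unit intensity).  Returns
    (normalized intensities, integer bins), binned by ceiling so a
    normalized signal in (i-1, i] lands in bin i and zero signal in bin 0 —
    the convention of the model's signal-bin distribution.
    """
    med = float(np.nanmedian(records["median_cytoplasmic_intensity"].to_numpy(dtype=float)))
    if not np.isfinite(med) or med <= 0:
        raise InvalidParameterError("dataset-wide cytoplasmic median must be > 0")
    norm = records["brightest_nuclear_intensity"].to_numpy(dtype=float) / med
    bins = np.ceil(norm - 1e-12).astype(np.int64)
    bins[norm <= 0] = 0
    return norm, bins


def assemble_mature_counts(records: pd.DataFrame, include_ts: bool = True) -> np.ndarray:
    """Mature mRNA counts per cell, excluding cells with zero detected spots.

    Zero-spot cells are dropped (they typically reflect segmentation or
    permeabilization failures, not silent cells).  With ``include_ts=False``
    one spot per cell — the transcription site — is subtracted, flooring at
    zero.
    """
    if len(records) == 0:
        raise InvalidParameterError("records must be non-empty")
    counts = records["spot_count"].to_numpy(dtype=np.int64)
    counts = counts[counts > 0]
    if not include_ts:
        counts = np.maximum(counts - 1, 0)
    return counts


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")
    for col in COLUMNS[1:-1]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise SchemaError(f"non-numeric value in column {col!r}")
        if (vals < 0).any():
            raise SchemaError(f"negative value in column {col!r}")
        df[col] = vals
    if not (df["spot_count"] == df["spot_count"].astype(np.int64)).all():
        raise SchemaError("non-integer value in column 'spot_count'")
    df["spot_count"] = df["spot_count"].astype(np.int64)
    bad = set(df["phase"].astype(str)) - _PHASES
    if bad:
        raise SchemaError(f"invalid phase label(s): {sorted(bad)}")
    return df[COLUMNS]


def load_cell_table(path) -> pd.DataFrame:
    """Load and schema-validate a cell table CSV."""
    return _validate(pd.read_csv(path))


def write_cell_table(records: pd.DataFrame, path) -> None:
    """Schema-validate and write a cell table CSV (round-trips with load)."""
    _validate(records.copy()).to_csv(path, index=False)
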