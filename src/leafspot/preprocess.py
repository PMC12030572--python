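"""Spectral preprocessing: replicate averaging, baseline removal, scaling.

Raman spectra of leaf tissue under 785 nm excitation ride on a broad
fluorescence background that must be estimated and subtracted before any
similarity or classification analysis. The baseline estimator here is an
iterative moving-average clipping smoother: starting from the raw spectrum,
each iteration replaces the running estimate by the pointwise minimum of
itself and its centred moving average. Narrow Raman peaks are progressively
shaved off while the smooth background survives, so the final estimate hugs
the valleys between peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .containers import SpectrumSet, ValidationError

log = logging.getLogger(__name__)

NormMethod = Literal["minmax", "vector_norm"]


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of the iterative moving-average baseline estimator.

    window
        Odd number of points of the centred moving average (default 31).
    iterations
        Number of smooth-and-clip passes (default 5).
    edge_mode
        Padding rule at the spectrum ends; ``reflect`` avoids the endpoint
        droop a truncated window would cause.
    """

    window: int = 31
    iterations: int = 5
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def average_replicates(spectra: SpectrumSet) -> SpectrumSet:
    """Average repeat acquisitions down to one spectrum per grid position.

    Requires a ``replicate_id`` metadata column; replicate groups may be
    unequal in size (the mean is over whatever is available). The averaged
    set keeps the first replicate's spectrum_id per position, drops the
    ``replicate_id`` column, and preserves first-appearance order.
    """
    meta = spectra.meta
    if "replicate_id" not in meta.columns:
        raise ValidationError("average_replicates needs a replicate_id metadata column")
    keys = ["leaf_id", "grid_row", "grid_col"]
    order = meta.drop_duplicates(subset=keys).index
    rows, recs = [], []
    grouped = meta.groupby(keys, sort=False)
    for first_idx in order:
        key = tuple(meta.loc[first_idx, k] for k in keys)
        idx = grouped.indices[key]
        if len(idx) == 0:  # pragma: no cover - groupby cannot yield empty
            raise ValidationError(f"no replicates for position {key}")
        rows.append(spectra.intensities[idx].mean(axis=0))
        rec = meta.loc[first_idx].drop(labels=["replicate_id"])
        recs.append(rec)
    import pandas as pd

    return SpectrumSet(
        wavenumbers=spectra.wavenumbers.copy(),
        intensities=np.vstack(rows),
        meta=pd.DataFrame(recs).reset_index(drop=True),
    )


def _moving_average(y: np.ndarray, window: int, edge_mode: str) -> np.ndarray:
    half = window // 2
    padded = np.pad(y, ((0, 0), (half, half)), mode=edge_mode)
    kernel = np.ones(window) / window
    # row-wise valid convolution via cumulative sums: fast and exact
    csum = np.cumsum(padded, axis=1)
    csum = np.concatenate([np.zeros((y.shape[0], 1)), csum], axis=1)
    return (csum[:, window:] - csum[:, :-window]) / window


def fit_baseline(intensity: np.ndarray, params: BaselineParams = BaselineParams()) -> np.ndarray:
    """Estimate the fluorescence baseline of one spectrum or a stack.

    Accepts a vector ``(n_channels,)`` or matrix ``(n, n_channels)`` and
    returns an array of the same shape. Raises if the spectrum is shorter
    than the smoothing window.
    """
    arr = np.asarray(intensity, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] < params.window:
        raise ValueError(
            f"spectrum length {arr.shape[1]} shorter than window {params.window}"
        )
    estimate = arr.copy()
    for _ in range(params.iterations):
        smoothed = _moving_average(estimate, params.window, params.edge_mode)
        estimate = np.minimum(estimate, smoothed)
    return estimate[0] if squeeze else estimate


def baseline_correct(
    spectra: SpectrumSet, params: BaselineParams = BaselineParams()
) -> SpectrumSet:
    """Subtract the fitted baseline from every spectrum, clipping at zero.

    Clipping keeps every corrected curve above the zero axis; metadata is
    unchanged.
    """
    baselines = fit_baseline(spectra.intensities, params)
    corrected = np.clip(spectra.intensities - baselines, 0.0, None)
    return spectra.with_intensities(corrected)


def normalize(spectra: SpectrumSet, method: NormMethod = "minmax") -> SpectrumSet:
    """Per-spectrum intensity scaling.

    ``minmax`` maps each row onto [0, 1]; ``vector_norm`` divides each row
    by its Euclidean norm (leaving cosine similarity unchanged). A constant
    row under minmax (or a zero row under vector_norm) becomes all zeros
    with a logged warning rather than an error.
    """
    x = spectra.intensities
    if method == "minmax":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        span = hi - lo
        flat = span[:, 0] == 0
        span[flat] = 1.0
        out = (x - lo) / span
        out[flat] = 0.0
    elif method == "vector_norm":
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        flat = norms[:, 0] == 0
        norms[flat] = 1.0
        out = x / norms
        out[flat] = 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if flat.any():
        ids = spectra.meta.loc[flat, "spectrum_id"].tolist()
        log.warning("constant/zero rows set to zeros during %s: %s", method, ids)
    return spectra.with_intensities(out)


def trim_range(spectra: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Restrict the wavenumber axis to [lo, hi] cm^-1 (inclusive)."""
    mask = (spectra.wavenumbers >= lo) & (spectra.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"no channels inside [{lo}, {hi}] cm^-1")
    return SpectrumSet(
        wavenumbers=spectra.wavenumbers[mask],
        intensities=spectra.intensities[:, mask],
        meta=spectra.meta.copy(),
    )


def preprocess(
    spectra: SpectrumSet,
    params: BaselineParams = BaselineParams(),
    method: NormMethod = "minmax",
    wavenumber_range: tuple[float, float] | None = None,
) -> SpectrumSet:
    """Full chain: optional replicate averaging, baseline removal, scaling."""
    if "replicate_id" in spectra.meta.columns:
        spectra = average_replicates(spectra)
    if wavenumber_range is not None:
        spectra = trim_range(spectra, *wavenumber_range)
    spectra = baseline_correct(spectra, params)
    return normalize(spectra, method)
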