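"""Cosine-similarity screening of leaf positions.

Each preprocessed spectrum is compared to the mean spectrum of its leaf by
the cosine of the angle between the two intensity vectors,

    cos(theta) = sum_i A_i B_i / (||A|| ||B||),

which is scale-free: it reflects the shape of the spectrum, not its
absolute intensity. Positions whose spectra point away from the leaf
consensus score low and are candidates for exclusion. Two thresholds are
used downstream: box-plot outliers (below Q1 - 1.5 IQR of a similarity
population) and the plain lower quartile (below Q1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SpectrumSet

Population = Literal["all", "per_leaf"]

#: Instrument-repeatability reference benchmark: the similarity level that
#: repeat acquisitions at a fixed position stay above, so positions scoring
#: lower than this differ by more than instrument noise.
STABILITY_FLOOR = 0.991


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two equal-length non-zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("vectors must be 1-D and of equal length >= 1")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def leaf_mean_spectrum(spectra: SpectrumSet, leaf_id) -> np.ndarray:
    """Channel-wise mean over all spectra of one leaf (the reference)."""
    return spectra.for_leaf(leaf_id).intensities.mean(axis=0)


def similarity_table(spectra: SpectrumSet) -> pd.DataFrame:
    """Per-spectrum cosine similarity to its leaf's mean spectrum.

    Returns one row per spectrum with metadata columns plus ``similarity``;
    the ``is_outlier`` / ``below_q1`` flags are added by
    :func:`boxplot_outliers`.
    """
    meta = spectra.meta
    sims = np.empty(spectra.n_spectra)
    for leaf_id in spectra.leaf_ids:
        mask = (meta["leaf_id"] == leaf_id).to_numpy()
        block = spectra.intensities[mask]
        ref = block.mean(axis=0)
        nref = np.linalg.norm(ref)
        norms = np.linalg.norm(block, axis=1)
        if nref == 0 or np.any(norms == 0):
            raise ValueError(f"zero-norm spectrum on leaf {leaf_id!r}")
        sims[mask] = block @ ref / (norms * nref)
    out = meta.loc[:, ["spectrum_id", "leaf_id", "group", "duration_h", "grid_row", "grid_col"]].copy()
    out["similarity"] = sims
    return out


def _q1_iqr(values: np.ndarray) -> tuple[float, float]:
    # linear-interpolation ("type 7") quantiles, the numpy default
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q1), float(q3 - q1)


def boxplot_outliers(
    sims: pd.DataFrame, population: Population = "all"
) -> tuple[pd.DataFrame, dict]:
    """Flag box-plot outliers and below-quartile rows of a similarity table.

    ``is_outlier`` marks similarities strictly below Q1 - 1.5 IQR of the
    chosen population (``all``: one pooled box plot; ``per_leaf``: one per
    leaf); ``below_q1`` marks those strictly below Q1 itself. Also returns
    a summary dict (min, max, mean, sd, Q1 on the pooled values).

    Each population must contain at least 4 values for quartiles to be
    meaningful.
    """
    sims = sims.copy()
    values = sims["similarity"].to_numpy()
    if population == "all":
        if len(values) < 4:
            raise ValueError("need >= 4 similarity values for box-plot statistics")
        q1, iqr = _q1_iqr(values)
        sims["is_outlier"] = values < q1 - 1.5 * iqr
        sims["below_q1"] = values < q1
    elif population == "per_leaf":
        sims["is_outlier"] = False
        sims["below_q1"] = False
        for leaf_id, sub in sims.groupby("leaf_id", sort=False):
            v = sub["similarity"].to_numpy()
            if len(v) < 4:
                raise ValueError(f"leaf {leaf_id!r} has < 4 spectra")
            q1, iqr = _q1_iqr(v)
            sims.loc[sub.index, "is_outlier"] = v < q1 - 1.5 * iqr
            sims.loc[sub.index, "below_q1"] = v < q1
    else:
        raise ValueError(f"unknown population {population!r}")
    pooled_q1, _ = _q1_iqr(values)
    summary = {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "q1": pooled_q1,
        "n": int(len(values)),
        "n_outliers": int(sims["is_outlier"].sum()),
        "n_below_q1": int(sims["below_q1"].sum()),
    }
    return sims, summary


# -- instrument repeatability --------------------------------------------


@dataclass
class RepeatabilityReport:
    """Minimum similarity of repeat acquisitions at fixed positions.

    ``minima`` is a table with one row per position and one column per
    collection count (each entry: the minimum similarity among the first
    ``k`` acquisitions, each compared to the mean of those ``k``);
    ``means`` are the cross-position means; ``passes_floor`` says whether
    every tabulated minimum stays at or above ``stability_floor``.
    """

    minima: pd.DataFrame
    means: pd.Series
    stability_floor: float
    passes_floor: bool


def repeatability_report(
    replicate_sims: Mapping[str, Sequence[np.ndarray]] | Mapping[str, np.ndarray],
    counts: Sequence[int] = (10, 20, 30),
    floor: float = STABILITY_FLOOR,
) -> RepeatabilityReport:
    """Summarize repeat-acquisition stability at a set of positions.

    ``replicate_sims`` maps a position label either to a stack of replicate
    spectra ``(n_replicates, n_channels)`` (similarities are computed
    against the prefix mean) or directly to a 1-D array of similarity
    values in acquisition order. If a position has fewer replicates than
    the largest requested count, the report is restricted to the counts
    available, with a warning.
    """
    counts = sorted(counts)
    rows: dict[str, dict[int, float]] = {}
    usable = set(counts)
    for pos, data in replicate_sims.items():
        arr = np.asarray(data, dtype=float)
        rows[pos] = {}
        for k in counts:
            if arr.shape[0] < k:
                warnings.warn(
                    f"position {pos!r} has only {arr.shape[0]} replicates; "
                    f"count {k} omitted"
                )
                usable.discard(k)
                continue
            prefix = arr[:k]
            if prefix.ndim == 2:
                ref = prefix.mean(axis=0)
                sims = prefix @ ref / (
                    np.linalg.norm(prefix, axis=1) * np.linalg.norm(ref)
                )
            else:
                sims = prefix
            rows[pos][k] = float(np.min(sims))
    minima = pd.DataFrame(rows).T.loc[:, sorted(usable)]
    means = minima.mean(axis=0)
    return RepeatabilityReport(
        minima=minima,
        means=means,
        stability_floor=floor,
        passes_floor=bool((minima.to_numpy() >= floor).all()),
    )
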