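"""Reading, writing and validating spectral tables and leaf grids.

Two plain-text dialects are supported:

``wide``
    CSV whose first column is ``wavenumber`` and each further column one
    spectrum (header = spectrum_id). The instrument-export convention.
``long``
    Tidy CSV with columns ``spectrum_id, wavenumber, intensity``.

Per-spectrum metadata travels in a sidecar CSV with columns
``spectrum_id, leaf_id, group, duration_h, grid_row, grid_col[, replicate_id]``.
Leaf grids are JSON documents. No wavenumber resampling is ever performed:
spectra with mismatched axes are an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .containers import (
    META_COLUMNS,
    LeafGrid,
    SpectrumSet,
    ValidationError,
)

Dialect = Literal["wide", "long"]

_FLOAT_FMT = "%.12g"  # text round-trip well below 1e-9 relative


def read_spectra_table(
    spectra_path: str | Path,
    meta_path: str | Path,
    dialect: Dialect = "wide",
) -> SpectrumSet:
    """Load a spectra table plus its metadata sidecar into a SpectrumSet.

    Raises :class:`ValidationError` on a non-monotone axis, axis mismatch
    between spectra, NaN intensities or missing metadata fields.
    """
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    meta = pd.read_csv(meta_path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata file {meta_path} missing columns {missing}")
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)

    if dialect == "wide":
        df = pd.read_csv(spectra_path)
        if df.columns[0] != "wavenumber":
            raise ValidationError("wide dialect requires first column 'wavenumber'")
        wavenumbers = df["wavenumber"].to_numpy(dtype=float)
        spectrum_ids = [str(c) for c in df.columns[1:]]
        intensities = df.iloc[:, 1:].to_numpy(dtype=float).T
    elif dialect == "long":
        df = pd.read_csv(spectra_path)
        required = {"spectrum_id", "wavenumber", "intensity"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long dialect requires columns {sorted(required)}")
        df["spectrum_id"] = df["spectrum_id"].astype(str)
        spectrum_ids = list(pd.unique(df["spectrum_id"]))
        axes = []
        rows = []
        for sid, sub in df.groupby("spectrum_id", sort=False):
            axes.append(sub["wavenumber"].to_numpy(dtype=float))
            rows.append(sub["intensity"].to_numpy(dtype=float))
        wavenumbers = axes[0]
        for ax in axes[1:]:
            if ax.shape != wavenumbers.shape or not np.array_equal(ax, wavenumbers):
                raise ValidationError("wavenumber axis differs between spectra")
        intensities = np.vstack(rows)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if np.isnan(intensities).any():
        raise ValidationError("NaN intensities in spectra table")

    meta = meta.set_index("spectrum_id")
    unknown = [s for s in spectrum_ids if s not in meta.index]
    if unknown:
        raise ValidationError(f"spectra without metadata: {unknown[:5]}")
    meta = meta.loc[spectrum_ids].reset_index()
    return SpectrumSet(wavenumbers=wavenumbers, intensities=intensities, meta=meta)


def write_spectra_table(
    spectra: SpectrumSet,
    spectra_path: str | Path,
    meta_path: str | Path,
    dialect: Dialect = "wide",
) -> None:
    """Write a SpectrumSet as spectra table + metadata sidecar.

    Round-trips through :func:`read_spectra_table` to <=1e-9 relative error.
    """
    if spectra.n_spectra == 0:
        raise ValidationError("refusing to write an empty SpectrumSet")
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    ids = spectra.meta["spectrum_id"].astype(str).tolist()
    if dialect == "wide":
        columns = {"wavenumber": spectra.wavenumbers}
        columns.update({sid: spectra.intensities[i] for i, sid in enumerate(ids)})
        pd.DataFrame(columns).to_csv(spectra_path, index=False, float_format=_FLOAT_FMT)
    elif dialect == "long":
        n = spectra.n_channels
        df = pd.DataFrame(
            {
                "spectrum_id": np.repeat(ids, n),
                "wavenumber": np.tile(spectra.wavenumbers, spectra.n_spectra),
                "intensity": spectra.intensities.ravel(),
            }
        )
        df.to_csv(spectra_path, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    spectra.meta.to_csv(meta_path, index=False)


# -- leaf grids ----------------------------------------------------------


def write_leaf_grids(grids: Iterable[LeafGrid], path: str | Path) -> None:
    """Serialize leaf grids to a single JSON document."""
    doc = [
        {
            "leaf_id": g.leaf_id,
            "spacing_cm": g.spacing_cm,
            "points": [
                {"grid_row": int(r), "grid_col": int(c), "region": reg}
                for r, c, reg in g.points[["grid_row", "grid_col", "region"]].itertuples(index=False)
            ],
        }
        for g in grids
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_leaf_grids(path: str | Path) -> list[LeafGrid]:
    doc = json.loads(Path(path).read_text())
    return [
        LeafGrid(
            leaf_id=entry["leaf_id"],
            spacing_cm=float(entry["spacing_cm"]),
            points=pd.DataFrame(entry["points"]),
        )
        for entry in doc
    ]


# -- validation report ---------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only consistency summary of a dataset against its grids."""

    per_leaf_counts: pd.Series
    orphan_spectra: pd.DataFrame  # spectra at positions absent from the grid
    orphan_points: pd.DataFrame  # grid points with no spectrum
    tabulation: pd.DataFrame  # spectrum counts, group x duration with margins

    @property
    def n_orphans(self) -> int:
        return len(self.orphan_spectra) + len(self.orphan_points)

    @property
    def total_spectra(self) -> int:
        return int(self.per_leaf_counts.sum())


def tabulate_counts(meta: pd.DataFrame, value: str | None = None) -> pd.DataFrame:
    """Group x duration contingency table with row/column margins.

    With ``value=None`` counts rows; otherwise sums the named column. The
    returned frame has durations as rows, groups as columns, and a ``Total``
    margin on both axes (the layout used for outlier tabulations).
    """
    from .containers import DURATIONS_H, GROUPS

    if value is None:
        tab = pd.crosstab(meta["duration_h"], meta["group"])
    else:
        tab = meta.pivot_table(
            index="duration_h", columns="group", values=value, aggfunc="sum", fill_value=0
        )
    tab = tab.reindex(index=sorted(tab.index), columns=[g for g in GROUPS if g in tab.columns])
    tab = tab.fillna(0).astype(int)
    tab["Total"] = tab.sum(axis=1)
    tab.loc["Total"] = tab.sum(axis=0)
    return tab


def validate_dataset(spectra: SpectrumSet, grids: Iterable[LeafGrid]) -> ValidationReport:
    """Cross-check spectra against leaf grids; never raises."""
    grids = list(grids)
    grid_points = {
        (g.leaf_id, int(r), int(c))
        for g in grids
        for r, c in g.points[["grid_row", "grid_col"]].itertuples(index=False)
    }
    meta = spectra.meta
    spec_points = set(
        zip(meta["leaf_id"], meta["grid_row"].astype(int), meta["grid_col"].astype(int))
    )
    orphan_mask = [
        (lid, int(r), int(c)) not in grid_points
        for lid, r, c in zip(meta["leaf_id"], meta["grid_row"], meta["grid_col"])
    ]
    orphan_spectra = meta.loc[orphan_mask, ["spectrum_id", "leaf_id", "grid_row", "grid_col"]]
    orphan_points = pd.DataFrame(
        [
            {"leaf_id": lid, "grid_row": r, "grid_col": c}
            for (lid, r, c) in sorted(grid_points - spec_points, key=str)
        ],
        columns=["leaf_id", "grid_row", "grid_col"],
    )
    return ValidationReport(
        per_leaf_counts=meta.groupby("leaf_id").size(),
        orphan_spectra=orphan_spectra.reset_index(drop=True),
        orphan_points=orphan_points,
        tabulation=tabulate_counts(meta),
    )
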