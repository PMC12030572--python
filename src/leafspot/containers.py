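"""Core in-memory containers for dot-matrix leaf Raman datasets.

A dataset is a stack of spectra acquired on a regular grid of positions
across one or more leaves, all sharing a single wavenumber axis, together
with per-spectrum metadata (leaf identity, treatment group, stress
duration, grid coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Treatment groups: control, N-deficient, P-deficient, K-deficient.
GROUPS = ("CK", "ND", "PD", "KD")
#: Stress durations in hours at which leaves are sampled.
DURATIONS_H = (24, 72, 120, 168)
#: Anatomical region labels assigned to grid positions.
REGIONS = ("margin", "vein", "base", "interior")

#: Metadata columns every SpectrumSet must carry (replicate_id optional).
META_COLUMNS = ("spectrum_id", "leaf_id", "group", "duration_h", "grid_row", "grid_col")


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class SpectrumSet:
    """A matrix of spectra on a common wavenumber axis plus metadata.

    Parameters
    ----------
    wavenumbers
        Strictly increasing spectral positions in cm^-1, shape ``(n_channels,)``.
    intensities
        One spectrum per row, shape ``(n_spectra, n_channels)``; arbitrary
        counts units, all finite.
    meta
        One record per row of ``intensities`` with at least the columns in
        :data:`META_COLUMNS`. An optional ``replicate_id`` column marks raw
        repeat acquisitions that still need averaging.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`ValidationError`."""
        wn = self.wavenumbers
        if wn.ndim != 1 or wn.size < 1:
            raise ValidationError("wavenumber axis must be a 1-D non-empty array")
        if np.any(np.diff(wn) <= 0):
            raise ValidationError("wavenumber axis must be strictly increasing")
        if self.intensities.shape[1] != wn.size:
            raise ValidationError(
                f"intensity rows have {self.intensities.shape[1]} channels, "
                f"axis has {wn.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite (no NaN/inf)")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns: {missing}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValidationError(
                f"{self.intensities.shape[0]} spectra but {len(self.meta)} metadata rows"
            )
        if self.meta["spectrum_id"].duplicated().any():
            raise ValidationError("spectrum_id values must be unique")
        # Positions must be unique once replicates have been averaged.
        if "replicate_id" not in self.meta.columns:
            dup = self.meta.duplicated(subset=["leaf_id", "grid_row", "grid_col"])
            if dup.any():
                bad = self.meta.loc[dup, ["leaf_id", "grid_row", "grid_col"]]
                raise ValidationError(
                    f"duplicated (leaf_id, grid_row, grid_col) positions:\n{bad}"
                )

    # -- convenience -----------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def leaf_ids(self) -> list:
        return list(pd.unique(self.meta["leaf_id"]))

    def select(self, mask: np.ndarray | pd.Series) -> "SpectrumSet":
        """Row-subset by boolean mask or positional index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def for_leaf(self, leaf_id) -> "SpectrumSet":
        mask = (self.meta["leaf_id"] == leaf_id).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown leaf_id {leaf_id!r}")
        return self.select(mask)

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """Copy of the set with intensity rows replaced, metadata unchanged."""
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=np.asarray(intensities, dtype=float),
            meta=self.meta.copy(),
        )

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.intensities, other.intensities)
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
        )


@dataclass
class LeafGrid:
    """Dot-matrix geometry of one leaf.

    ``points`` lists the in-leaf grid cells with an anatomical region label;
    cells not listed are outside the leaf. Grid row 0 is at the leaf base
    (petiole end) and column 0 abuts the main vein; the physical position of
    a cell is ``index * spacing_cm``.
    """

    leaf_id: str
    spacing_cm: float
    points: pd.DataFrame  # columns: grid_row, grid_col, region

    def __post_init__(self) -> None:
        if not isinstance(self.points, pd.DataFrame):
            self.points = pd.DataFrame(self.points, columns=["grid_row", "grid_col", "region"])
        self.points = self.points.reset_index(drop=True)
        if self.spacing_cm <= 0:
            raise ValidationError("spacing_cm must be positive")
        bad = set(self.points["region"]) - set(REGIONS)
        if bad:
            raise ValidationError(f"unknown region labels: {sorted(bad)}")
        if self.points.duplicated(subset=["grid_row", "grid_col"]).any():
            raise ValidationError("duplicated grid cells in LeafGrid.points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding grid."""
        return (
            int(self.points["grid_row"].max()) + 1,
            int(self.points["grid_col"].max()) + 1,
        )

    def leaf_mask(self) -> np.ndarray:
        """Boolean membership matrix over the bounding grid."""
        mask = np.zeros(self.shape(), dtype=bool)
        mask[self.points["grid_row"].to_numpy(), self.points["grid_col"].to_numpy()] = True
        return mask

    def region_of(self) -> dict[tuple[int, int], str]:
        return {
            (int(r), int(c)): reg
            for r, c, reg in self.points[["grid_row", "grid_col", "region"]].itertuples(index=False)
        }

    def contains(self, grid_row: int, grid_col: int) -> bool:
        m = (self.points["grid_row"] == grid_row) & (self.points["grid_col"] == grid_col)
        return bool(m.any())
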