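"""Spatial projection of similarity values onto the leaf grid.

Low-similarity positions are what matter spatially, so the map keeps the
actual similarity value only where a position falls below the lower
quartile and replaces every other in-leaf position with 1.0; cells outside
the leaf are missing (NaN). Region enrichment then asks whether flagged
positions concentrate at the leaf margins, near the main vein, or at the
base, relative to how many grid cells each region offers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .containers import REGIONS, LeafGrid

MapFormat = Literal["csv_matrix", "png_heatmap"]


def assign_regions(cells: set[tuple[int, int]], base_rows: int = 2, vein_cols: int = 2) -> dict[tuple[int, int], str]:
    """Deterministic anatomical region labels for a set of in-leaf cells.

    margin: any in-leaf cell with at least one 4-neighbour outside the leaf;
    vein: cells in the first ``vein_cols`` columns (adjacent to the main
    vein, which runs along column 0); base: cells in the ``base_rows``
    occupied rows nearest the petiole (lowest row indices the leaf
    reaches); interior: the rest. Precedence margin > vein > base.
    """
    regions = {}
    min_row = min(r for (r, _) in cells)
    for (r, c) in cells:
        neighbours = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
        if any(n not in cells for n in neighbours):
            regions[(r, c)] = "margin"
        elif c < vein_cols:
            regions[(r, c)] = "vein"
        elif r < min_row + base_rows:
            regions[(r, c)] = "base"
        else:
            regions[(r, c)] = "interior"
    return regions


@dataclass
class SimilarityMap:
    """Masked similarity matrix over one leaf's bounding grid.

    In-leaf cells at or above the lower quartile hold 1.0; below-quartile
    cells hold their similarity; out-of-leaf cells hold NaN.
    """

    leaf_id: str
    values: np.ndarray  # (n_rows, n_cols), NaN outside the leaf

    @property
    def n_flagged(self) -> int:
        with np.errstate(invalid="ignore"):
            return int(np.nansum(self.values < 1.0))

    def in_leaf(self) -> np.ndarray:
        return ~np.isnan(self.values)


def build_similarity_map(sims: pd.DataFrame, grid: LeafGrid) -> SimilarityMap:
    """Project one leaf's flagged similarity rows onto its grid.

    ``sims`` must carry a ``below_q1`` column (see
    :func:`leafspot.similarity.boxplot_outliers`) and cover only positions
    present in the grid; an unknown position is an error.
    """
    sub = sims[sims["leaf_id"] == grid.leaf_id]
    if "below_q1" not in sub.columns:
        raise ValueError("similarity table lacks below_q1 flags; run boxplot_outliers first")
    values = np.full(grid.shape(), np.nan)
    in_leaf = grid.leaf_mask()
    values[in_leaf] = 1.0
    for row in sub.itertuples(index=False):
        r, c = int(row.grid_row), int(row.grid_col)
        if not (0 <= r < values.shape[0] and 0 <= c < values.shape[1]) or not in_leaf[r, c]:
            raise ValueError(
                f"spectrum {row.spectrum_id} at ({r}, {c}) is not an in-leaf grid point"
            )
        if row.below_q1:
            values[r, c] = row.similarity
    return SimilarityMap(leaf_id=grid.leaf_id, values=values)


def region_enrichment(
    maps: Iterable[SimilarityMap], grids: Iterable[LeafGrid]
) -> pd.DataFrame:
    """Per-region concentration of below-quartile positions across leaves.

    For each region: the number of grid cells available, the number
    flagged, the fraction of all flags landing there, the fraction of all
    cells it contributes, and the enrichment ratio
    ``fraction_flagged / fraction_available`` (NaN when there are no flags).
    """
    grid_by_leaf = {g.leaf_id: g for g in grids}
    avail = {r: 0 for r in REGIONS}
    flagged = {r: 0 for r in REGIONS}
    for m in maps:
        grid = grid_by_leaf[m.leaf_id]
        region_of = grid.region_of()
        for (r, c), reg in region_of.items():
            avail[reg] += 1
            if not np.isnan(m.values[r, c]) and m.values[r, c] < 1.0:
                flagged[reg] += 1
    total_avail = sum(avail.values())
    total_flagged = sum(flagged.values())
    rows = []
    for reg in REGIONS:
        fa = avail[reg] / total_avail if total_avail else np.nan
        ff = flagged[reg] / total_flagged if total_flagged else np.nan
        rows.append(
            {
                "region": reg,
                "n_available": avail[reg],
                "n_flagged": flagged[reg],
                "fraction_available": fa,
                "fraction_flagged": ff,
                "enrichment": ff / fa if total_flagged and fa else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def export_map(smap: SimilarityMap, path: str | Path, fmt: MapFormat = "csv_matrix") -> None:
    """Write a similarity map as a CSV matrix or a PNG heat map.

    The CSV uses empty fields for out-of-leaf cells and round-trips through
    :func:`read_map`. The PNG uses a monotone scale where values closer to
    1.0 render darker (flagged, low-similarity cells stand out bright).
    """
    path = Path(path)
    if fmt == "csv_matrix":
        pd.DataFrame(smap.values).to_csv(path, index=False, header=False, float_format="%.12g")
    elif fmt == "png_heatmap":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(smap.values, cmap="Greys", vmin=0.9, vmax=1.0, origin="lower")
        ax.set_xlabel("grid column (from main vein)")
        ax.set_ylabel("grid row (from base)")
        ax.set_title(f"leaf {smap.leaf_id}")
        fig.colorbar(im, ax=ax, label="cosine similarity")
        fig.savefig(path, dpi=120)
        plt.close(fig)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_map(path: str | Path, leaf_id: str) -> SimilarityMap:
    values = pd.read_csv(Path(path), header=None).to_numpy(dtype=float)
    return SimilarityMap(leaf_id=leaf_id, values=values)
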