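import numpy as np
import pandas as pd
import pytest

from leafspot import SpectrumSet, LeafGrid


def make_meta(n, leaf_id="L1", group="CK", duration_h=24, start=0):
    return pd.DataFrame(
        {
            "spectrum_id": [f"{leaf_id}_s{start + i}" for i in range(n)],
            "leaf_id": leaf_id,
            "group": group,
            "duration_h": duration_h,
            "grid_row": [(start + i) // 4 for i in range(n)],
            "grid_col": [(start + i) % 4 for i in range(n)],
        }
    )


@pytest.fixture
def tiny_set():
    """Two spectra on a 3-channel axis, one leaf."""
    return SpectrumSet(
        wavenumbers=np.array([200.0, 201.0, 202.0]),
        intensities=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        meta=make_meta(2),
    )


@pytest.fixture
def two_leaf_set():
    """Eight spectra over two leaves with distinct intensities."""
    rng = np.random.default_rng(42)
    meta = pd.concat(
        [make_meta(4, "L1", "CK"), make_meta(4, "L2", "ND", start=4)],
        ignore_index=True,
    )
    return SpectrumSet(
        wavenumbers=np.linspace(200, 400, 16),
        intensities=rng.uniform(1.0, 10.0, (8, 16)),
        meta=meta,
    )


@pytest.fixture
def square_grid():
    """A 3x3 fully occupied leaf grid (all cells margin by adjacency)."""
    points = pd.DataFrame(
        [
            {"grid_row": r, "grid_col": c, "region": "margin"}
            for r in range(3)
            for c in range(3)
        ]
    )
    return LeafGrid(leaf_id="L1", spacing_cm=1.0, points=points)
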