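"""Per-leaf exclusion of low-similarity spectra.

Each leaf's similarity distribution defines its own lower quantile
threshold (default the quartile, q = 0.25); spectra strictly below the
threshold are excluded so ties at the threshold are kept. Leaves with
fewer than 4 spectra pass through uncleansed — a quartile of so few values
is unstable — with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectrumSet
from .similarity import Population


@dataclass
class CleansingResult:
    kept: SpectrumSet
    excluded_ids: list[str]
    rule: str
    per_leaf: pd.DataFrame  # columns: before, excluded, after

    def __post_init__(self) -> None:
        bad = self.per_leaf[
            self.per_leaf["before"] != self.per_leaf["excluded"] + self.per_leaf["after"]
        ]
        if len(bad):
            raise AssertionError(f"cleansing ledger does not balance:\n{bad}")


def cleanse(
    spectra: SpectrumSet,
    sims: pd.DataFrame,
    q: float = 0.25,
    population: Population = "per_leaf",
) -> CleansingResult:
    """Drop spectra whose similarity falls strictly below the q-quantile.

    ``population='per_leaf'`` computes the threshold within each leaf (the
    default); ``'all'`` uses one pooled threshold. ``sims`` must cover every
    spectrum in the set. Deterministic given its inputs.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    sim_by_id = sims.set_index("spectrum_id")["similarity"]
    ids = spectra.meta["spectrum_id"]
    missing = ids[~ids.isin(sim_by_id.index)]
    if len(missing):
        raise ValueError(f"similarity table does not cover spectra: {missing.tolist()[:5]}")
    values = sim_by_id.loc[ids].to_numpy()
    exclude = np.zeros(len(ids), dtype=bool)
    if population == "all":
        thr = np.quantile(values, q)
        exclude = values < thr
    elif population == "per_leaf":
        for leaf_id in spectra.leaf_ids:
            mask = (spectra.meta["leaf_id"] == leaf_id).to_numpy()
            v = values[mask]
            if mask.sum() < 4:
                warnings.warn(
                    f"leaf {leaf_id!r} has {mask.sum()} spectra; quantile unstable, "
                    "leaf passed through uncleansed"
                )
                continue
            thr = np.quantile(v, q)
            exclude[mask] = v < thr
    else:
        raise ValueError(f"unknown population {population!r}")
    kept = spectra.select(~exclude)
    per_leaf = (
        pd.DataFrame(
            {
                "leaf_id": spectra.meta["leaf_id"],
                "excluded": exclude,
            }
        )
        .groupby("leaf_id")
        .agg(before=("excluded", "size"), excluded=("excluded", "sum"))
    )
    per_leaf["after"] = per_leaf["before"] - per_leaf["excluded"]
    return CleansingResult(
        kept=kept,
        excluded_ids=ids[exclude].tolist(),
        rule=f"similarity < Q(q={q}) of {population} population (strict)",
        per_leaf=per_leaf,
    )
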