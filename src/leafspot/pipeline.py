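"""End-to-end orchestration: simulate/load -> preprocess -> similarity ->
map -> cleanse -> classify, with one consolidated, seedable report.

The report bundles the dataset validation summary, the pooled similarity
statistics (min/max/mean/sd/Q1), outlier tabulations by group x duration,
the region-enrichment table, the cleansing ledger and the per-duration
before/after model comparison. Everything downstream of the seed is
deterministic, so a run is reproducible from its serialized config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .cleanse import cleanse
from .containers import LeafGrid, SpectrumSet
from .mapping import build_similarity_map, region_enrichment
from .plsda import before_after_comparison
from .preprocess import BaselineParams, preprocess
from .similarity import boxplot_outliers, similarity_table
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    seed: int = 0
    # input: either simulate, or load from disk
    simulate: bool = True
    # overrides for SyntheticConfig fields (e.g. {"n_leaves": 2})
    synthetic: dict = field(default_factory=dict)
    spectra_path: str | None = None
    meta_path: str | None = None
    grids_path: str | None = None
    dialect: str = "wide"
    # preprocessing
    baseline_window: int = 31
    baseline_iterations: int = 5
    normalize_method: str = "minmax"
    wavenumber_range: tuple[float, float] | None = None
    # similarity / outliers
    outlier_population: str = "all"
    map_population: str = "per_leaf"
    # cleansing
    cleanse_enabled: bool = True
    cleanse_q: float = 0.25
    cleanse_population: str = "per_leaf"
    # model
    kfold: int = 5
    lv_max: int = 15
    tau: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if data.get("wavenumber_range") is not None:
            data["wavenumber_range"] = tuple(data["wavenumber_range"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["wavenumber_range"] is not None:
            d["wavenumber_range"] = list(d["wavenumber_range"])
        return d


@dataclass
class RunReport:
    config: dict
    validation: dict
    similarity_summary: dict
    outlier_tabulation: pd.DataFrame
    below_q1_tabulation: pd.DataFrame
    enrichment: pd.DataFrame
    cleansing_per_leaf: pd.DataFrame | None
    comparison: pd.DataFrame | None
    stage_log: list[dict]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "config": self.config,
            "validation": self.validation,
            "similarity_summary": self.similarity_summary,
            "outlier_tabulation": _frame_doc(self.outlier_tabulation),
            "below_q1_tabulation": _frame_doc(self.below_q1_tabulation),
            "enrichment": _frame_doc(self.enrichment.reset_index()),
            "cleansing_per_leaf": (
                _frame_doc(self.cleansing_per_leaf.reset_index())
                if self.cleansing_per_leaf is not None
                else None
            ),
            "comparison": (
                _frame_doc(self.comparison) if self.comparison is not None else None
            ),
            "stage_log": self.stage_log,
        }
        text = json.dumps(doc, indent=1, default=_json_default, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = ["# leafspot run report", ""]
        s = self.similarity_summary
        lines += [
            "## Similarity (pooled)",
            f"n = {s['n']}, min = {s['min']:.5f}, max = {s['max']:.5f}, "
            f"mean = {s['mean']:.5f}, sd = {s['sd']:.5f}, Q1 = {s['q1']:.5f}",
            f"box-plot outliers: {s['n_outliers']}; below Q1: {s['n_below_q1']}",
            "",
            "## Outliers by group x duration",
            self.outlier_tabulation.to_markdown(),
            "",
            "## Region enrichment of below-quartile positions",
            self.enrichment.to_markdown(floatfmt=".3f"),
            "",
        ]
        if self.comparison is not None:
            lines += [
                "## Model before vs. after cleansing",
                self.comparison.to_markdown(index=False, floatfmt=".2f"),
                "",
            ]
        return "\n".join(lines)


def _frame_doc(df: pd.DataFrame) -> dict:
    return json.loads(df.to_json(orient="split"))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage in order on simulated or on-disk data."""
    stage_log: list[dict] = []

    def _log(stage: str, **info):
        stage_log.append({"stage": stage, **info})
        log.info("%s: %s", stage, info)

    if cfg.simulate:
        syn = SyntheticConfig(seed=cfg.seed, **cfg.synthetic)
        raw, grids, truth = generate_dataset(syn)
        _log("simulate", n_spectra=raw.n_spectra, n_leaves=len(grids), seed=cfg.seed)
    else:
        if not (cfg.spectra_path and cfg.meta_path and cfg.grids_path):
            raise ValueError("need spectra/meta/grids paths when simulate is off")
        raw = lio.read_spectra_table(cfg.spectra_path, cfg.meta_path, cfg.dialect)
        grids = lio.read_leaf_grids(cfg.grids_path)
        _log("load", n_spectra=raw.n_spectra, n_leaves=len(grids))

    report_val = lio.validate_dataset(raw, grids)
    validation = {
        "n_spectra": report_val.total_spectra,
        "n_orphan_spectra": len(report_val.orphan_spectra),
        "n_orphan_points": len(report_val.orphan_points),
        "tabulation": _frame_doc(report_val.tabulation),
    }
    _log("validate", n_orphans=report_val.n_orphans)

    params = BaselineParams(window=cfg.baseline_window, iterations=cfg.baseline_iterations)
    pre = preprocess(
        raw, params, cfg.normalize_method, wavenumber_range=cfg.wavenumber_range
    )
    _log("preprocess", n_spectra=pre.n_spectra, window=params.window,
         iterations=params.iterations, normalize=cfg.normalize_method)

    sims = similarity_table(pre)
    sims_flagged, summary = boxplot_outliers(sims, population=cfg.outlier_population)
    out_tab = lio.tabulate_counts(
        sims_flagged.assign(flag=sims_flagged["is_outlier"].astype(int)), value="flag"
    )
    q1_tab = lio.tabulate_counts(
        sims_flagged.assign(flag=sims_flagged["below_q1"].astype(int)), value="flag"
    )
    _log("similarity", **{k: summary[k] for k in ("n", "min", "mean", "n_outliers")})

    map_sims, _ = boxplot_outliers(sims, population=cfg.map_population)
    maps = [build_similarity_map(map_sims, g) for g in grids]
    enrichment = region_enrichment(maps, grids)
    _log("map", n_maps=len(maps), n_flagged=int(sum(m.n_flagged for m in maps)))

    cleansing_per_leaf = None
    comparison = None
    if cfg.cleanse_enabled:
        result = cleanse(pre, sims, q=cfg.cleanse_q, population=cfg.cleanse_population)
        cleansing_per_leaf = result.per_leaf
        _log("cleanse", n_before=pre.n_spectra, n_after=result.kept.n_spectra,
             n_excluded=len(result.excluded_ids))
        comparison = before_after_comparison(
            pre, result.kept, k=cfg.kfold, lv_max=cfg.lv_max, tau=cfg.tau, seed=cfg.seed
        )
        _log("train", n_rows=len(comparison))

    return RunReport(
        config=cfg.to_dict(),
        validation=validation,
        similarity_summary=summary,
        outlier_tabulation=out_tab,
        below_q1_tabulation=q1_tab,
        enrichment=enrichment,
        cleansing_per_leaf=cleansing_per_leaf,
        comparison=comparison,
        stage_log=stage_log,
    )
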