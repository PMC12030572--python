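"""Synthetic dot-matrix leaf Raman datasets with known ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: a broad fluorescence baseline, a fixed library of 20
characteristic leaf Raman peaks, treatment-group-dependent peak-intensity
signatures that deepen with stress duration, mild position-to-position
compositional jitter, region-localized anomalous positions (concentrated
at the leaf margin, then near the main vein and base, strongest at 24 h
and decaying by 168 h), and per-acquisition instrument noise calibrated so
repeat acquisitions at one position stay above the 0.991 similarity
benchmark.

Leaves are half-ellipse lattices on the main-vein side of the leaf: grid
column 0 runs along the vein, row 0 sits at the base, and cells outside
the ellipse are off-leaf. Anomalies perturb a random subset of peak
amplitudes multiplicatively and add a local baseline bump; they lower the
cosine similarity of the position without changing its class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DURATIONS_H, GROUPS, LeafGrid, SpectrumSet
from .mapping import assign_regions

#: Characteristic Raman peak centers of cucumber leaf tissue (cm^-1):
#: pectin, cellulose, carotenoid, phenylpropanoid, protein and aliphatic
#: bands between 700 and 3200 cm^-1.
PEAK_CENTERS = (
    747.0, 917.0, 1005.0, 1048.0, 1080.0, 1117.0, 1155.0, 1185.0, 1218.0,
    1265.0, 1288.0, 1301.0, 1327.0, 1387.0, 1440.0, 1488.0, 1528.0,
    1611.0, 1674.0, 3191.0,
)

#: Base peak amplitudes (counts): carotenoid bands (1005, 1155, 1528)
#: dominate, the CH-stretch region (3191) is moderate.
PEAK_AMPLITUDES = (
    320.0, 280.0, 900.0, 420.0, 360.0, 300.0, 820.0, 260.0, 340.0, 310.0,
    300.0, 330.0, 380.0, 290.0, 520.0, 310.0, 780.0, 360.0, 420.0, 600.0,
)

#: Multiplicative peak-intensity signatures per deficiency, indexed by
#: position in PEAK_CENTERS; values are the fully developed (168 h) effect.
GROUP_EFFECTS: dict[str, dict[int, float]] = {
    "CK": {},
    "ND": {2: 0.70, 6: 0.75, 16: 0.65, 18: 0.70, 12: 1.25},
    "PD": {3: 0.70, 7: 0.72, 13: 0.68, 4: 1.30},
    "KD": {0: 0.70, 14: 0.68, 19: 0.72, 10: 1.30},
}

#: How much of the full group signature is expressed at each duration:
#: stress effects deepen over time, so 24 h is the hardest to classify.
EFFECT_RAMP = {24: 0.6, 72: 0.8, 120: 0.9, 168: 1.0}

#: Fraction of each region's positions rendered anomalous at 24 h
#: (margin > vein ~ base >> interior, the spatial pattern the screening
#: is meant to recover).
ANOMALY_REGION_FRACTIONS = {"margin": 0.50, "vein": 0.35, "base": 0.35, "interior": 0.03}

#: Decay of the anomaly rate with stress duration (anomalies are most
#: frequent at 24 h and nearly vanish by 168 h).
ANOMALY_DURATION_DECAY = {24: 1.0, 72: 0.30, 120: 0.25, 168: 0.12}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the synthetic leaf-scan study."""

    seed: int = 0
    n_leaves: int = 3  # leaves per group x duration cell
    grid_rows: int = 8
    grid_cols: int = 6
    spacing_cm: float = 1.0
    wn_min: float = 200.0
    wn_max: float = 3400.0
    wn_step: float = 4.0
    peak_centers: tuple[float, ...] = PEAK_CENTERS
    peak_amplitudes: tuple[float, ...] = PEAK_AMPLITUDES
    peak_sigma: float = 5.0  # cm^-1; keeps the 1288/1301 pair resolved
    group_effects: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: GROUP_EFFECTS
    )
    effect_ramp: Mapping[int, float] = field(default_factory=lambda: EFFECT_RAMP)
    baseline_amp: float = 3000.0  # counts at the fluorescence hump
    baseline_mu: float = 300.0  # hump position in (wn - 150) coordinates
    baseline_width: float = 1.2  # log-width of the hump
    position_jitter: float = 0.02  # per-position peak-amplitude jitter (rel.)
    leaf_scale_sigma: float = 0.08  # per-leaf overall intensity scale (log-sd)
    anomaly_fractions: Mapping[str, float] = field(
        default_factory=lambda: ANOMALY_REGION_FRACTIONS
    )
    anomaly_decay: Mapping[int, float] = field(
        default_factory=lambda: ANOMALY_DURATION_DECAY
    )
    anomaly_peak_prob: float = 0.5  # chance each peak joins the perturbed subset
    anomaly_suppress_lo: float = 0.35  # multiplicative range for perturbed peaks
    anomaly_suppress_hi: float = 0.75
    anomaly_bump_frac: float = 0.15  # local baseline bump, rel. baseline_amp
    noise_sd: float = 10.0  # per-acquisition additive noise (counts)
    n_acquisitions: int = 3  # averaged per position, as acquired
    durations: tuple[int, ...] = DURATIONS_H
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        if len(self.peak_centers) != len(self.peak_amplitudes):
            raise ValueError("peak_centers and peak_amplitudes must align")
        if any(not 0 <= f <= 1 for f in self.anomaly_fractions.values()):
            raise ValueError("anomaly fractions must lie in [0, 1]")
        if min(self.peak_amplitudes) <= 0 or self.baseline_amp <= 0:
            raise ValueError("amplitudes must be positive")

    def wavenumbers(self) -> np.ndarray:
        n = int(round((self.wn_max - self.wn_min) / self.wn_step)) + 1
        return self.wn_min + self.wn_step * np.arange(n)


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle-style checks."""

    positions: pd.DataFrame  # spectrum_id, leaf_id, group, duration_h, region, is_anomalous
    peak_centers: tuple[float, ...]
    config: SyntheticConfig

    @property
    def anomalous_ids(self) -> list[str]:
        return self.positions.loc[self.positions["is_anomalous"], "spectrum_id"].tolist()


# -- building blocks ------------------------------------------------------


def fluorescence_baseline(cfg: SyntheticConfig, amplitude: float | None = None) -> np.ndarray:
    """Broad log-normal-shaped fluorescence hump peaking near 400 cm^-1."""
    wn = cfg.wavenumbers()
    x = wn - 150.0
    shape = np.exp(-np.log(x / cfg.baseline_mu) ** 2 / (2 * cfg.baseline_width**2))
    return (cfg.baseline_amp if amplitude is None else amplitude) * shape


def peak_profile(cfg: SyntheticConfig, amplitudes: Sequence[float]) -> np.ndarray:
    """Sum of Gaussian peaks with the given amplitudes on the config axis."""
    wn = cfg.wavenumbers()
    centers = np.asarray(cfg.peak_centers)
    out = np.zeros_like(wn)
    for c, a in zip(centers, amplitudes):
        out += a * np.exp(-((wn - c) ** 2) / (2 * cfg.peak_sigma**2))
    return out


def _group_amplitudes(cfg: SyntheticConfig, group: str, duration_h: int) -> np.ndarray:
    """Peak amplitudes with the duration-ramped group signature applied."""
    amps = np.asarray(cfg.peak_amplitudes, dtype=float).copy()
    ramp = cfg.effect_ramp[duration_h]
    for idx, mult in cfg.group_effects.get(group, {}).items():
        amps[idx] *= 1.0 + ramp * (mult - 1.0)
    return amps


def _leaf_cells(cfg: SyntheticConfig, scale: float) -> set[tuple[int, int]]:
    """Half-ellipse lattice: vein along column 0, base at row 0."""
    cells = set()
    a = scale * cfg.grid_rows / 2.0  # semi-axis along the vein
    b = scale * cfg.grid_cols  # semi-axis across the blade
    for r in range(cfg.grid_rows):
        for c in range(cfg.grid_cols):
            y = (r + 0.5 - cfg.grid_rows / 2.0) / a
            x = (c + 0.5) / b
            if x * x + y * y <= 1.0:
                cells.add((r, c))
    return cells


# -- main entry points ----------------------------------------------------


def generate_dataset(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[SpectrumSet, list[LeafGrid], GroundTruth]:
    """Simulate the full study: all groups, durations and leaves.

    Spectra are per-position means of ``n_acquisitions`` noisy acquisitions
    (generated directly with noise scaled by 1/sqrt(n_acquisitions)).
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    wn = cfg.wavenumbers()
    rows, meta_records, truth_records, grids = [], [], [], []
    for duration_h in cfg.durations:
        for group in cfg.groups:
            base_amps = _group_amplitudes(cfg, group, duration_h)
            for leaf_i in range(cfg.n_leaves):
                leaf_id = f"{group}_{duration_h}h_L{leaf_i + 1}"
                leaf_scale = float(np.exp(rng.normal(0.0, cfg.leaf_scale_sigma)))
                ellipse_scale = float(rng.uniform(0.82, 0.96))
                cells = _leaf_cells(cfg, ellipse_scale)
                if len(cells) < 8:
                    raise ValueError("leaf grid too small; increase grid_rows/grid_cols")
                regions = assign_regions(cells)
                baseline = fluorescence_baseline(
                    cfg, cfg.baseline_amp * float(rng.uniform(0.85, 1.15))
                )
                grids.append(
                    LeafGrid(
                        leaf_id=leaf_id,
                        spacing_cm=cfg.spacing_cm,
                        points=pd.DataFrame(
                            [
                                {"grid_row": r, "grid_col": c, "region": regions[(r, c)]}
                                for (r, c) in sorted(cells)
                            ]
                        ),
                    )
                )
                decay = cfg.anomaly_decay[duration_h]
                for (r, c) in sorted(cells):
                    region = regions[(r, c)]
                    p_anom = cfg.anomaly_fractions[region] * decay
                    is_anom = bool(rng.random() < p_anom)
                    amps = (
                        base_amps
                        * leaf_scale
                        * (1.0 + rng.normal(0.0, cfg.position_jitter, len(base_amps)))
                    )
                    spectrum = baseline.copy()
                    if is_anom:
                        subset = rng.random(len(amps)) < cfg.anomaly_peak_prob
                        if not subset.any():
                            subset[rng.integers(len(amps))] = True
                        factors = rng.uniform(
                            cfg.anomaly_suppress_lo, cfg.anomaly_suppress_hi, len(amps)
                        )
                        amps = np.where(subset, amps * factors, amps)
                        bump_center = rng.uniform(800.0, 1800.0)
                        bump_sigma = rng.uniform(60.0, 120.0)
                        spectrum += (
                            cfg.anomaly_bump_frac
                            * cfg.baseline_amp
                            * np.exp(-((wn - bump_center) ** 2) / (2 * bump_sigma**2))
                        )
                    spectrum = spectrum + peak_profile(cfg, amps)
                    noise = rng.normal(
                        0.0, cfg.noise_sd / np.sqrt(cfg.n_acquisitions), wn.size
                    )
                    sid = f"{leaf_id}_r{r}c{c}"
                    rows.append(spectrum + noise)
                    meta_records.append(
                        {
                            "spectrum_id": sid,
                            "leaf_id": leaf_id,
                            "group": group,
                            "duration_h": duration_h,
                            "grid_row": r,
                            "grid_col": c,
                        }
                    )
                    truth_records.append(
                        {
                            "spectrum_id": sid,
                            "leaf_id": leaf_id,
                            "group": group,
                            "duration_h": duration_h,
                            "region": region,
                            "is_anomalous": is_anom,
                        }
                    )
    spectra = SpectrumSet(
        wavenumbers=wn,
        intensities=np.vstack(rows),
        meta=pd.DataFrame(meta_records),
    )
    truth = GroundTruth(
        positions=pd.DataFrame(truth_records),
        peak_centers=cfg.peak_centers,
        config=cfg,
    )
    return spectra, grids, truth


def generate_replicate_stream(
    cfg: SyntheticConfig = SyntheticConfig(),
    position: int = 0,
    n: int = 30,
) -> np.ndarray:
    """``n`` raw re-acquisitions of one fixed position's true spectrum.

    ``position`` seeds the position-specific composition so different
    positions have different (but internally fixed) true spectra; each
    acquisition adds fresh instrument noise at ``noise_sd``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng((cfg.seed, position))
    amps = np.asarray(cfg.peak_amplitudes) * (
        1.0 + rng.normal(0.0, cfg.position_jitter, len(cfg.peak_amplitudes))
    )
    truth = fluorescence_baseline(cfg) + peak_profile(cfg, amps)
    return truth[None, :] + rng.normal(0.0, cfg.noise_sd, (n, truth.size))
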