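"""Leaf N/P/K content calculators (g per kg dry weight).

Nitrogen is determined by Kjeldahl titration, phosphorus by
molybdenum-antimony colorimetry and potassium by flame photometry; these
pure functions turn the bench readings into dry-weight contents. The
factor 0.014 g/mL is the mass of N neutralized by 1 mL of 1 mol/L sulfuric
acid titrant.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class KjeldahlInput:
    """Titration readings for the Kjeldahl nitrogen determination.

    c: acid concentration (mol/L); V2/V0: titrant volumes for sample and
    blank (mL); V1: distilled aliquot volume (mL); V: total test-solution
    volume (mL); m: dry sample mass (g).
    """

    c: float
    V2: float
    V0: float
    V1: float
    V: float
    m: float

    def __post_init__(self) -> None:
        if min(self.V1, self.V) <= 0 or self.m <= 0:
            raise ValueError("volumes and mass must be positive")
        if self.V1 > self.V:
            raise ValueError("aliquot volume V1 cannot exceed total volume V")
        if self.V2 < self.V0:
            raise ValueError("sample titrant volume below blank (V2 < V0)")


@dataclass(frozen=True)
class ColorimetricInput:
    """Readings for the P (colorimetric) and K (flame photometric) assays.

    rho: analyte mass concentration (mg/L); rho0: blank concentration
    (mg/L, used for K only); V: total volume (mL); V1: dispensed volume
    (mL); V2: colour-solution volume (mL); m: dry sample mass (g).
    """

    rho: float
    V: float
    V1: float
    V2: float
    m: float
    rho0: float = 0.0

    def __post_init__(self) -> None:
        if min(self.V, self.V1, self.V2) <= 0 or self.m <= 0:
            raise ValueError("volumes and mass must be positive")
        if not self.rho >= self.rho0 >= 0:
            raise ValueError("need rho >= rho0 >= 0")


def nitrogen_content(inp: KjeldahlInput) -> float:
    """Total N in g/kg dry weight from Kjeldahl titration volumes."""
    return (inp.V2 - inp.V0) * inp.c * 0.014 / (inp.m * (inp.V1 / inp.V)) * 100


def phosphorus_content(inp: ColorimetricInput) -> float:
    """Total P in g/kg dry weight from the colorimetric reading."""
    return inp.rho * (inp.V / inp.m) * (inp.V2 / inp.V1) * 1e-4


def potassium_content(inp: ColorimetricInput) -> float:
    """Total K in g/kg dry weight, blank-corrected flame-photometer reading.

    Identical to the P formula with rho replaced by (rho - rho0).
    """
    return (inp.rho - inp.rho0) * (inp.V / inp.m) * (inp.V2 / inp.V1) * 1e-4
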