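"""Potency-to-free-energy conversion and fold-change resistance cutoffs.

A mutation that weakens inhibitor binding by a factor *f* in IC50 (or Ki)
shifts the binding free energy by ΔΔG = RT·ln f; at 298.15 K a 10-fold loss
is 1.36 kcal/mol, the operating definition of resistance used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ThermoConstants
from .records import DeltaDeltaG

RESISTANT = "resistant"
SUSCEPTIBLE = "susceptible"


@dataclass(frozen=True)
class MichaelisContext:
    """ATP concentration and Michaelis constant for competition correction.

    ``S0`` and ``KM`` must share units. In the KM >> S0 limit IC50 ≈ Ki and
    the correction vanishes.
    """

    S0: float
    KM: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError(f"S0 must be non-negative, got {self.S0}")
        if self.KM <= 0:
            raise ValueError(f"KM must be positive, got {self.KM}")


@dataclass(frozen=True)
class ClassificationThreshold:
    """A fold-change resistance cutoff expressed in energy units.

    ``cutoff`` keeps full precision for classification; ``reported`` gives
    the 2-decimal value used in reports, which follows the convention of
    quoting larger cutoffs as multiples of the rounded one-decade constant
    (RT·ln10 ≈ 1.36 kcal/mol), so 10/20/100-fold read 1.36/1.77/2.72.
    """

    fold: float
    cutoff: float
    constants: ThermoConstants

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError(f"fold must exceed 1, got {self.fold}")

    @property
    def reported(self) -> float:
        decade = round(self.constants.RT * math.log(10.0), 2)
        return round(decade * math.log10(self.fold), 2)

    @classmethod
    def from_fold(
        cls, fold: float, constants: ThermoConstants | None = None
    ) -> "ClassificationThreshold":
        return cutoff_from_fold(fold, constants)


def ki_from_ic50(ic50: float, ctx: MichaelisContext) -> float:
    """Inhibition constant from IC50 under ATP competition.

    Uses IC50 = Ki / (1 + S0/KM), i.e. Ki = IC50 * (1 + S0/KM). Note this
    correction factor is inverted relative to the textbook Cheng–Prusoff
    relation (see docs/methods.md); both coincide when KM >> S0, the regime
    assumed for the relative free energies computed here.
    """
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return ic50 * (1.0 + ctx.S0 / ctx.KM)


def ddg_from_potencies(
    wt: float, mut: float, constants: ThermoConstants | None = None
) -> float:
    """ΔΔG = −RT·ln(IC50_WT / IC50_mut) in kcal/mol.

    Positive when the mutant is less potently inhibited (mut > wt);
    antisymmetric under swapping wild-type and mutant.
    """
    constants = constants or ThermoConstants()
    if wt <= 0 or mut <= 0:
        raise ValueError("potencies must be positive concentrations")
    return -constants.RT * math.log(wt / mut)


def ddg_from_pic50(
    pic50_wt: float, pic50_mut: float, constants: ThermoConstants | None = None
) -> float:
    """ΔΔG = RT·ln10·(pIC50_WT − pIC50_mut); equivalent to ddg_from_potencies."""
    constants = constants or ThermoConstants()
    return constants.RT * math.log(10.0) * (pic50_wt - pic50_mut)


def cutoff_from_fold(
    fold: float, constants: ThermoConstants | None = None
) -> ClassificationThreshold:
    """Energy cutoff RT·ln(fold) for a fold-change resistance definition."""
    constants = constants or ThermoConstants()
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    return ClassificationThreshold(fold, constants.RT * math.log(fold), constants)


def classify(ddg: DeltaDeltaG, threshold: ClassificationThreshold) -> str:
    """Call a mutation resistant or susceptible.

    Resistant iff ΔΔG > cutoff (ties are susceptible: "ΔΔG ≤ cutoff" defines
    the susceptible class) or the value is a censored lower bound — an assay
    that saturated its dynamic range demonstrates resistance by itself.
    """
    if ddg.censored or ddg.value > threshold.cutoff:
        return RESISTANT
    return SUSCEPTIBLE


def combined_error(sigma_a: float, sigma_b: float) -> float:
    """Quadrature combination √(σ_a² + σ_b²) of independent error components."""
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("error components must be non-negative")
    return math.hypot(sigma_a, sigma_b)
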