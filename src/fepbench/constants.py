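"""Thermodynamic constants shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

#: Ideal gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant, temperature and assumed forcefield error.

    The default temperature of 298.15 K reproduces the published fold-change
    cutoffs (10-fold -> 1.36 kcal/mol, 20-fold -> 1.77, 100-fold -> 2.72);
    ``sigma_ff`` is the forcefield error treated as a random error component
    when drawing combined error bars.
    """

    R: float = GAS_CONSTANT_KCAL
    T: float = 298.15
    sigma_ff: float = 0.9

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.R <= 0:
            raise ValueError(f"gas constant must be positive, got {self.R}")
        if self.sigma_ff < 0:
            raise ValueError(f"sigma_ff must be non-negative, got {self.sigma_ff}")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.R * self.T
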