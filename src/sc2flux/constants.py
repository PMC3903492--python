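"""Physical constants and the study's default experimental conditions.

Concentrations are handled in molar units internally (M); the public
interfaces accept mM, µM or nM with explicit conversion helpers rather
than implicit unit guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Molecular weight of the SC-2 peptidoglycan carrier (kDa).
SC2_MW_KDA: float = 841.0

#: Standard carrier dose, 1 mg/mL of an 841-kDa species (mM).
SC2_DOSE_MM: float = 1.0 / SC2_MW_KDA  # = 1.1891e-3 mM

#: Initial total extracellular lignan concentration in the uptake assays (µM).
C0_UM: float = 100.0

#: Cells seeded per dish: 1e5 cells/mL in 2 mL of medium.
SEEDED_CELLS: float = 2e5

#: Uptake sampling grid (min).
SAMPLE_TIMES_MIN: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class ThermoConstants:
    """Thermodynamic constants for the free-energy ledger.

    Parameters
    ----------
    R : float
        Gas constant, J K⁻¹ mol⁻¹.
    T : float
        Absolute temperature, K.  Defaults to 310 K (37 °C, the
        incubation temperature of the cell assays).
    N_A : float
        Avogadro constant, mol⁻¹.
    """

    R: float = 8.314
    T: float = 310.0
    N_A: float = 6.02e23

    def __post_init__(self) -> None:
        for name in ("R", "T", "N_A"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def RT(self) -> float:
        """R·T in J mol⁻¹."""
        return self.R * self.T


DEFAULT_CONSTANTS = ThermoConstants()
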