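"""Free-energy ledger for carrier-mediated transmembrane transport.

The carrier-assisted path is resolved into four sequential steps:

1. carrier + outer membrane → membrane-bound carrier complex,
2. membrane-bound carrier + extracellular lignan → loaded complex,
3. translocation: outer-membrane lignan pool C_om → inner-membrane pool
   C_mA′ (the peak intracellular concentration),
4. irreversible intracellular degradation of the delivered lignan.

Each step is assigned a pseudo-equilibrium quotient K_eq from a species
concentration snapshot (the :class:`TransportState`), converted to a step
free energy, and summed into an overall path free energy.  Degenerate
snapshots are first-class: a vanishing denominator species with a finite
numerator yields K_eq = +∞, and the ledger arithmetic treats ±∞ as
explicit extended-real values — an infinity is never produced by silent
floating-point overflow, and a sum mixing +∞ with −∞ raises rather than
returning a number.

Because the outer-membrane concentration is far in excess of the carrier
it is treated as a constant K folded into the step-1 quotient
(K_eq′ = K_eq·K), so step 1 needs no membrane magnitude; K defaults to 1.

Two free-energy conventions are provided.  ``"ln"`` is the standard
ΔG = −RT·ln K_eq.  ``"table6"`` is a documented reproduction mode,
ΔG = −RT·K_eq (no logarithm), which matches the source ledger this
module reconstructs; that ledger also lists a negative K_eq for step 3,
which only the product form accepts.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .errors import (
    IndeterminateSumError,
    InfeasibleBalanceError,
    UndefinedQuotientError,
    ValidationError,
)

__all__ = [
    "TransportState",
    "FreeEnergyStep",
    "FreeEnergyLedger",
    "DEFAULT_STOICHIOMETRY",
    "molar_from_mass_conc",
    "complexation_balance",
    "partition_at_peak",
    "step_keq",
    "free_energy",
    "overall_free_energy",
    "coverage_fmol_per_cell",
    "particles_per_cell",
]

_CONC_FIELDS = (
    "sc2_free",
    "m_outer",
    "sc2_mouter",
    "sc2_mouter_ls",
    "ls_free",
    "ls_in",
    "c0",
    "c_om",
    "c_mA",
    "c_mA_prime",
    "c_fl",
    "c_mE",
)


@dataclass(frozen=True)
class TransportState:
    """Species-concentration snapshot at pseudo-equilibrium (all in M).

    ``m_outer`` is the outer-membrane binding-site pool, treated as the
    constant K (default 1, unitless magnitude) since it is in vast excess
    over the carrier.  ``c_mA`` defaults to ``c_mA_prime`` under the
    usual approximation C_mA ≈ C_mA′.  Path geometry (``x1``, ``x2``)
    and the kinetic constants k₄–k₉ are carried as metadata only; the
    ledger never uses them.
    """

    lignan: str = ""
    sc2_free: float = 0.0
    m_outer: float = 1.0
    sc2_mouter: float = 0.0
    sc2_mouter_ls: float = 0.0
    ls_free: float = 0.0
    ls_in: float = 0.0
    c0: float = 0.0
    c_om: float = 0.0
    c_mA: float | None = None
    c_mA_prime: float = 0.0
    c_fl: float = 0.0
    c_mE: float = 0.0
    x1: float | None = None
    x2: float | None = None
    rate_constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _CONC_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.c_mA is None:
            object.__setattr__(self, "c_mA", self.c_mA_prime)
        if self.c0 > 0 and abs(self.c_om + self.c_mA_prime - self.c0) > 1e-9:
            raise ValidationError(
                "mass balance violated: c_om + c_mA_prime must equal c0 "
                f"({self.c_om} + {self.c_mA_prime} != {self.c0})"
            )

    def species(self, name: str) -> float:
        """Resolve a species name, including the derived names used by the
        default step stoichiometry: ``ls_degraded`` (= ls_in − c_mE, the
        amount consumed by intracellular degradation) and
        ``ls_reversible`` (the reverse-reaction pool of the irreversible
        degradation step, identically 0)."""
        if name == "ls_degraded":
            return self.ls_in - self.c_mE
        if name == "ls_reversible":
            return 0.0
        if name in _CONC_FIELDS:
            return float(getattr(self, name))
        raise ValidationError(f"unknown species {name!r}")


#: Default mass-action reading of the four transport steps: for each step,
#: (numerator species, denominator species) of the pseudo-equilibrium
#: quotient.  Step 1 uses the membrane-folded form K_eq' = K_eq * K;
#: step 4 encodes irreversibility through an empty reverse pool.
DEFAULT_STOICHIOMETRY: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {
    1: (("sc2_mouter",), ("sc2_free",)),
    2: (("sc2_mouter_ls",), ("sc2_mouter", "ls_free")),
    3: (("c_mA_prime",), ("c_om",)),
    4: (("ls_degraded",), ("ls_reversible",)),
}


def molar_from_mass_conc(mass_conc_mg_per_mL: float, mw_kDa: float) -> float:
    """Convert a mass concentration (mg/mL) to mM given the MW in kDa.

    mg/mL equals g/L, and kDa equals kg/mol, so the molarity in mM is
    simply mass_conc/mw.
    """
    if mw_kDa <= 0:
        raise ValidationError("molecular weight must be positive")
    if mass_conc_mg_per_mL < 0:
        raise ValidationError("mass concentration must be non-negative")
    return mass_conc_mg_per_mL / mw_kDa


def complexation_balance(
    total_ls_M: float, carrier_M: float, stoichiometry: float = 1.0
) -> float:
    """Free lignan left after full 1:stoichiometry carrier loading (M).

    At pseudo-equilibrium the membrane-bound carrier is completely
    lignan-loaded, so free lignan = total − stoichiometry·carrier.
    """
    bound = stoichiometry * carrier_M
    if total_ls_M < bound:
        raise InfeasibleBalanceError(
            f"total lignan {total_ls_M} M < bound {bound} M"
        )
    return total_ls_M - bound


def partition_at_peak(c0_mM: float, u_peak_mM: float) -> tuple[float, float]:
    """Partition the initial pool at peak uptake: (C_om, C_mA′) in mM.

    The peak intracellular concentration is taken as C_mA′ (≈ C_mA) and
    the remainder of the initial extracellular pool as C_om, so the two
    always balance to C₀ exactly.
    """
    if u_peak_mM < 0:
        raise ValidationError("peak uptake must be non-negative")
    if u_peak_mM > c0_mM:
        raise InfeasibleBalanceError(
            f"peak uptake {u_peak_mM} mM exceeds initial pool {c0_mM} mM"
        )
    return c0_mM - u_peak_mM, u_peak_mM


def step_keq(
    state: TransportState,
    step: int,
    *,
    stoichiometry: Mapping[int, tuple[Sequence[str], Sequence[str]]] | None = None,
) -> float:
    """Pseudo-equilibrium quotient for one transport step (extended real).

    The quotient is Π(numerator species)/Π(denominator species) under
    the configured stoichiometry (default:
    :data:`DEFAULT_STOICHIOMETRY`).  A zero denominator with a positive
    numerator yields +∞ (−∞ for a negative numerator, which can arise
    from the signed difference species of step 4); 0/0 raises
    :class:`~sc2flux.errors.UndefinedQuotientError`.
    """
    table = DEFAULT_STOICHIOMETRY if stoichiometry is None else stoichiometry
    if step not in table:
        raise ValidationError(f"no stoichiometry configured for step {step}")
    num_names, den_names = table[step]
    num = math.prod(state.species(n) for n in num_names)
    den = math.prod(state.species(n) for n in den_names)
    if den == 0.0:
        if num > 0.0:
            return math.inf
        if num < 0.0:
            return -math.inf
        raise UndefinedQuotientError(
            f"step {step}: all participating species vanish (0/0)"
        )
    return num / den


def free_energy(
    keq: float,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    mode: str = "ln",
) -> float:
    """Step free energy in J from an extended-real K_eq.

    mode ``"ln"``: ΔG = −RT·ln K_eq (K_eq must be positive; +∞ maps to
    −∞ and 0⁺ maps to +∞).  mode ``"table6"``: ΔG = −RT·K_eq, the
    product form of the reproduction ledger, defined for any extended
    real including negative K_eq.
    """
    rt = constants.RT
    if mode == "ln":
        if keq == math.inf:
            return -math.inf
        if keq == 0.0:
            return math.inf
        if keq < 0.0 or keq == -math.inf:
            raise ValidationError(
                f"K_eq = {keq} is outside the domain of the ln convention; "
                "a negative quotient is only meaningful in the 'table6' "
                "product convention"
            )
        return -rt * math.log(keq)
    if mode == "table6":
        if keq == math.inf:
            return -math.inf
        if keq == -math.inf:
            return math.inf
        return -rt * keq
    raise ValidationError(f"unknown free-energy mode {mode!r}")


def overall_free_energy(steps: Sequence[float]) -> float:
    """Absorbing-infinity sum of step free energies (J).

    Any −∞ term drives the sum to −∞ provided no +∞ term is present
    (and symmetrically); a ledger containing both raises
    :class:`~sc2flux.errors.IndeterminateSumError`.
    """
    has_pos = any(x == math.inf for x in steps)
    has_neg = any(x == -math.inf for x in steps)
    if has_pos and has_neg:
        raise IndeterminateSumError(
            "ledger contains both +inf and -inf step free energies"
        )
    if has_pos:
        return math.inf
    if has_neg:
        return -math.inf
    return float(sum(steps))


@dataclass(frozen=True)
class FreeEnergyStep:
    step: int
    keq: float
    delta_g_J: float
    mode: str


@dataclass(frozen=True)
class FreeEnergyLedger:
    """Per-step K_eq and ΔG plus the overall path free energy."""

    lignan: str
    steps: tuple[FreeEnergyStep, ...]
    constants: ThermoConstants = DEFAULT_CONSTANTS

    @classmethod
    def from_state(
        cls,
        state: TransportState,
        *,
        constants: ThermoConstants = DEFAULT_CONSTANTS,
        mode: str = "ln",
        keq_overrides: Mapping[int, float] | None = None,
        stoichiometry: Mapping[int, tuple[Sequence[str], Sequence[str]]] | None = None,
    ) -> "FreeEnergyLedger":
        """Build the four-step ledger from a pseudo-equilibrium state.

        ``keq_overrides`` replaces the mass-action quotient of selected
        steps with externally supplied constants (the route by which a
        printed ledger is reproduced when its defining algebra is not
        available).
        """
        overrides = keq_overrides or {}
        table = DEFAULT_STOICHIOMETRY if stoichiometry is None else stoichiometry
        steps = []
        for s in sorted(table):
            keq = (
                float(overrides[s])
                if s in overrides
                else step_keq(state, s, stoichiometry=table)
            )
            steps.append(
                FreeEnergyStep(s, keq, free_energy(keq, constants, mode), mode)
            )
        return cls(state.lignan, tuple(steps), constants)

    @property
    def overall_J(self) -> float:
        return overall_free_energy([s.delta_g_J for s in self.steps])

    def to_dict(self) -> dict:
        """JSON-safe representation; ±∞ serialises as "+inf"/"-inf"."""
        return {
            "lignan": self.lignan,
            "steps": [
                {
                    "step": s.step,
                    "keq": _ext(s.keq),
                    "delta_g_J": _ext(s.delta_g_J),
                    "mode": s.mode,
                }
                for s in self.steps
            ],
            "overall_J": _ext(self.overall_J),
        }

    def summary(self) -> str:
        lines = [
            f"Transport free-energy ledger: {self.lignan or '(unnamed)'}",
            "=" * 52,
            f"{'step':>4}  {'K_eq':>12}  {'dG (kJ)':>12}  mode",
        ]
        for s in self.steps:
            dg = s.delta_g_J / 1000.0 if math.isfinite(s.delta_g_J) else s.delta_g_J
            lines.append(
                f"{s.step:>4}  {_fmt(s.keq):>12}  {_fmt(dg):>12}  {s.mode}"
            )
        ov = self.overall_J
        ov_kJ = ov / 1000.0 if math.isfinite(ov) else ov
        lines.append("-" * 52)
        lines.append(f"overall: {_fmt(ov_kJ)} kJ")
        return "\n".join(lines)


def _ext(x: float):
    if x == math.inf:
        return "+inf"
    if x == -math.inf:
        return "-inf"
    return float(x)


def _fmt(x: float) -> str:
    if x == math.inf:
        return "+inf"
    if x == -math.inf:
        return "-inf"
    return f"{x:.4g}"


def coverage_fmol_per_cell(
    final_conc_ug_per_mL: float,
    volume_mL: float,
    n_cells: float,
    mw_kDa: float,
) -> float:
    """Carrier coverage per cell in fmol from a dosing bookkeeping.

    Total carrier mass = concentration × volume; divided by the molar
    mass it gives moles, expressed in fmol and divided by the cell count.
    """
    if final_conc_ug_per_mL < 0:
        raise ValidationError("final concentration must be non-negative")
    if volume_mL <= 0 or mw_kDa <= 0:
        raise ValidationError("volume and molecular weight must be positive")
    if n_cells <= 0:
        raise ValidationError("cell count must be positive")
    mass_g = final_conc_ug_per_mL * 1e-6 * volume_mL
    mol = mass_g / (mw_kDa * 1000.0)
    return mol * 1e15 / n_cells


def particles_per_cell(
    fmol_per_cell: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert a per-cell molar coverage (fmol) to particle count."""
    if fmol_per_cell < 0:
        raise ValidationError("coverage must be non-negative")
    return fmol_per_cell * 1e-15 * constants.N_A
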