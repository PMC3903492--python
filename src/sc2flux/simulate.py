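"""Synthetic assay-data generators.

Two generators reproduce the statistical structure the estimators
assume, so the whole pipeline is testable without laboratory data:

* :func:`gen_uptake` — an uptake time course from a two-pool scheme with
  an instantaneous-adsorption offset: the extracellular pool feeds the
  intracellular pool (first-order in the remaining extracellular
  concentration, or at a constant transfer rate, depending on the model
  flavour) while the intracellular pool decays first-order at the
  elimination rate.  The offset U₀ captures the rapid initial adsorption
  that leaves uptake nonzero as t → 0; a positive elimination rate
  produces the rise-to-plateau-then-decline shape of the real assays.
* :func:`gen_dose_response` — viability curves from a descending
  four-parameter logistic, optionally with a low-dose proliferative
  (hormesis) bump, over a two-fold dose series.

Noise is additive Gaussian per sampled point, seeded through
``numpy.random.default_rng`` so the same seed reproduces the same curve
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import C0_UM, SAMPLE_TIMES_MIN, SEEDED_CELLS
from .doseresponse import DoseResponseCurve, four_param_logistic
from .errors import ValidationError
from .kinetics import UptakeTimeCourse, _uptake_closed_form

__all__ = ["UptakeSimSpec", "DoseResponseSimSpec", "gen_uptake", "gen_dose_response"]


@dataclass(frozen=True)
class UptakeSimSpec:
    """Parameters of one simulated uptake time course.

    Defaults mirror the study conditions: C₀ = 100 µM of lignan, an
    instantaneous-adsorption offset of 47 µM (the observed t = 0
    uptake), sampling at {0, 5, 15, 30, 60, 90, 120} min and Gaussian
    noise of SD 3 µM (the middle of the 2–5 µM replicate scatter).

    ``model`` selects the transfer flavour: ``"first_order"`` takes
    ``transfer_rate`` in min⁻¹ applied to the remaining extracellular
    concentration; ``"constant"`` takes it in µM·min⁻¹ as a zero-order
    source.
    """

    C0_uM: float = C0_UM
    U0_uM: float = 47.0
    transfer_rate: float = 0.01
    elimination_rate: float = 0.005
    carrier_dose_mM: float = 0.0
    sample_times: tuple[float, ...] = SAMPLE_TIMES_MIN
    noise_sd: float = 3.0
    seed: int = 0
    model: str = "first_order"
    lignan: str = "synthetic"

    def __post_init__(self) -> None:
        if self.C0_uM <= 0:
            raise ValidationError("C0_uM must be positive")
        if not 0 <= self.U0_uM <= self.C0_uM:
            raise ValidationError("U0_uM must lie in [0, C0_uM]")
        t = np.asarray(self.sample_times, dtype=float)
        if len(t) == 0 or t[0] < 0 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise ValidationError(
                "sample_times must be strictly increasing with first >= 0"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.transfer_rate < 0 or self.elimination_rate < 0:
            raise ValidationError("rates must be non-negative")
        if self.model not in ("first_order", "constant"):
            raise ValidationError("model must be 'first_order' or 'constant'")


def uptake_mean_curve(spec: UptakeSimSpec, times: np.ndarray) -> np.ndarray:
    """Noiseless solution of the generating ODE at arbitrary times (µM)."""
    t = np.asarray(times, dtype=float)
    if spec.model == "first_order":
        # the adsorbed offset U0 is already out of the medium, so the
        # transferable extracellular source starts at C0 - U0
        return _uptake_closed_form(
            t,
            spec.transfer_rate,
            spec.C0_uM - spec.U0_uM,
            spec.U0_uM,
            spec.elimination_rate,
        )
    # constant-rate source: dU/dt = r - ke*U
    r, ke, U0 = spec.transfer_rate, spec.elimination_rate, spec.U0_uM
    if ke == 0.0:
        return U0 + r * t
    return r / ke + (U0 - r / ke) * np.exp(-ke * t)


def gen_uptake(spec: UptakeSimSpec) -> UptakeTimeCourse:
    """Simulate one uptake time course per the spec (seeded, reproducible)."""
    t = np.asarray(spec.sample_times, dtype=float)
    u = uptake_mean_curve(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        u = u + rng.normal(0.0, spec.noise_sd, size=u.shape)
    u = np.clip(u, 0.0, None)
    return UptakeTimeCourse.from_arrays(
        spec.lignan,
        t,
        u,
        C0_uM=spec.C0_uM,
        carrier_dose_mM=spec.carrier_dose_mM,
        sd=[spec.noise_sd] * len(t) if spec.noise_sd > 0 else None,
    )


def _two_fold_doses(lo: float = 0.02, n: int = 8) -> tuple[float, ...]:
    return tuple(lo * 2.0**k for k in range(n))


@dataclass(frozen=True)
class DoseResponseSimSpec:
    """Parameters of one simulated viability curve.

    Defaults: a two-fold dose series 0.02–2.56 mM spanning the IC50s of
    the three lignans (0.07–0.64 mM), top 100% / bottom 0% asymptotes,
    Hill slope 1.5, replicate noise SD 5% and 2×10⁵ seeded cells.  The
    optional hormesis bump peaks at ``hormesis_peak_mM`` (default
    0.08 mM, inside the <0.16 mM proliferative window) and vanishes at
    dose 0 so the control stays at the top asymptote.
    """

    ic50_mM: float = 0.55
    hill: float = 1.5
    doses: tuple[float, ...] = field(default_factory=_two_fold_doses)
    top: float = 100.0
    bottom: float = 0.0
    hormesis_amplitude: float = 0.0
    hormesis_peak_mM: float = 0.08
    noise_sd: float = 5.0
    seeded_cells: float = SEEDED_CELLS
    seed: int = 0
    compound: str = "synthetic"
    carrier: bool = False
    incubation_h: float = 48.0

    def __post_init__(self) -> None:
        if self.ic50_mM <= 0:
            raise ValidationError("ic50_mM must be positive")
        d = np.asarray(self.doses, dtype=float)
        if len(d) == 0 or d[0] <= 0 or (len(d) > 1 and not np.all(np.diff(d) > 0)):
            raise ValidationError("doses must be strictly increasing and positive")
        if not 0 <= self.bottom < self.top:
            raise ValidationError("asymptotes must satisfy 0 <= bottom < top")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.hill <= 0:
            raise ValidationError("hill must be positive")
        if self.hormesis_peak_mM <= 0:
            raise ValidationError("hormesis_peak_mM must be positive")


def viability_mean_curve(spec: DoseResponseSimSpec, doses: np.ndarray) -> np.ndarray:
    """Noiseless viability (%) at arbitrary doses: 4PL plus hormesis bump."""
    d = np.asarray(doses, dtype=float)
    v = four_param_logistic(d, spec.top, spec.bottom, spec.ic50_mM, spec.hill)
    if spec.hormesis_amplitude:
        x = d / spec.hormesis_peak_mM
        v = v + spec.hormesis_amplitude * x * np.exp(1.0 - x)
    return np.asarray(v, dtype=float)


def gen_dose_response(spec: DoseResponseSimSpec) -> DoseResponseCurve:
    """Simulate one viability curve per the spec (seeded, reproducible)."""
    d = np.asarray(spec.doses, dtype=float)
    v = viability_mean_curve(spec, d)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    v = np.clip(v, 0.0, None)
    return DoseResponseCurve.from_arrays(
        spec.compound,
        d,
        v,
        carrier=spec.carrier,
        incubation_h=spec.incubation_h,
        sd=[spec.noise_sd] * len(d) if spec.noise_sd > 0 else None,
        seeded_cells=spec.seeded_cells,
    )
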