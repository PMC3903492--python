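"""Interval-wise uptake-rate estimation for lignan time courses.

The cellular-uptake experiments sample intracellular lignan concentration
U(t) (µM) on a fixed grid of incubation times while the cells sit in a
medium of known initial total lignan concentration C₀.  Free-lignan uptake
is summarised by per-interval first-order coefficients

    k₁(tᵢ) = (Uᵢ − Uᵢ₋₁) / ((tᵢ − tᵢ₋₁) · C₀)        [min⁻¹]

i.e. the mean uptake rate over the interval normalised by the initial
total concentration.  With the peptidoglycan carrier present at dose S the
uptake is treated as second order in lignan and carrier, and the
per-interval coefficient becomes

    k₂(tᵢ) = k₁(tᵢ) / S_nM                           [L·mmol⁻¹·min⁻¹]

where S_nM is the carrier dose expressed in nM (S_mM · 10⁶).  The nM
expression of S is a deliberate unit reconciliation: the carrier dose is
conventionally quoted in mM, but the second-order column of the reference
rate tables is only consistent with the nM reading (see docs/methods.md).

Negative coefficients mark the post-peak intracellular decay phase.

The module exposes both plain functions (`fit_first_order_rates`, ...)
and a model/results pair (`UptakeKinetics` / `UptakeKineticsResults`)
that bundles the full per-curve analysis with a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CarrierRequiredError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "UptakePoint",
    "UptakeTimeCourse",
    "RateCoefficientSeries",
    "fit_first_order_rates",
    "fit_second_order_rates",
    "detect_peak",
    "decay_phase_rates",
    "simulate_uptake_curve",
    "UptakeKinetics",
    "UptakeKineticsResults",
]

#: nM per mM — the unit reconciliation applied to the carrier dose when
#: forming second-order coefficients.
_MM_TO_NM = 1e6


@dataclass(frozen=True)
class UptakePoint:
    """One sampled point of an uptake time course."""

    time_min: float
    uptake_uM: float
    sd_uM: float | None = None
    extrapolated: bool = False


@dataclass(frozen=True)
class UptakeTimeCourse:
    """Intracellular concentration of one lignan versus incubation time.

    Parameters
    ----------
    lignan : str
        Compound identifier (e.g. ``"SB"`` for schisandrin B).
    carrier_dose_mM : float
        Carrier concentration S in mM; 0 for the carrier-free assay.
    C0_uM : float
        Initial total extracellular lignan concentration (µM).
    points : tuple of UptakePoint
        Samples ordered by strictly increasing time.
    """

    lignan: str
    carrier_dose_mM: float
    C0_uM: float
    points: tuple[UptakePoint, ...]

    def __post_init__(self) -> None:
        if self.C0_uM <= 0:
            raise ValidationError("C0_uM must be positive")
        if self.carrier_dose_mM < 0:
            raise ValidationError("carrier_dose_mM must be non-negative")
        times = self.times
        if len(times) and not np.all(np.diff(times) > 0):
            raise ValidationError("sample times must be strictly increasing")
        for p in self.points:
            if p.uptake_uM < 0:
                raise ValidationError("uptake values must be non-negative")
            # Soft plausibility check: uptake exceeding the initial total
            # concentration by more than 3 SD suggests a unit mix-up.
            sd = p.sd_uM or 0.0
            if p.uptake_uM > self.C0_uM + 3.0 * sd:
                warnings.warn(
                    f"uptake {p.uptake_uM} µM at t={p.time_min} min exceeds "
                    f"C0={self.C0_uM} µM + 3·sd",
                    stacklevel=3,
                )

    @classmethod
    def from_arrays(
        cls,
        lignan: str,
        times: Sequence[float],
        uptake: Sequence[float],
        *,
        C0_uM: float,
        carrier_dose_mM: float = 0.0,
        sd: Sequence[float] | None = None,
        extrapolated: Iterable[bool] | None = None,
    ) -> "UptakeTimeCourse":
        times = list(times)
        uptake = list(uptake)
        if len(times) != len(uptake):
            raise ValidationError("times and uptake must have equal length")
        sds: list[float | None] = list(sd) if sd is not None else [None] * len(times)
        flags = list(extrapolated) if extrapolated is not None else [False] * len(times)
        pts = tuple(
            UptakePoint(float(t), float(u), None if s is None else float(s), bool(f))
            for t, u, s, f in zip(times, uptake, sds, flags)
        )
        return cls(lignan, float(carrier_dose_mM), float(C0_uM), pts)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_min for p in self.points], dtype=float)

    @property
    def uptake(self) -> np.ndarray:
        return np.array([p.uptake_uM for p in self.points], dtype=float)

    @property
    def has_carrier(self) -> bool:
        return self.carrier_dose_mM > 0

    def uptake_at(self, time_min: float) -> float:
        """Return the sampled uptake at an exact sampling time (µM)."""
        for p in self.points:
            if p.time_min == time_min:
                return p.uptake_uM
        raise KeyError(f"no sample at t={time_min} min")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lignan": self.lignan,
                "carrier_dose_mM": self.carrier_dose_mM,
                "time_min": self.times,
                "uptake_uM": self.uptake,
                "sd_uM": [p.sd_uM for p in self.points],
                "extrapolated": [p.extrapolated for p in self.points],
            }
        )


@dataclass(frozen=True)
class RateInterval:
    """One interval's rate coefficient, reported at the interval end."""

    t_start: float
    t_end: float
    value: float


@dataclass(frozen=True)
class RateCoefficientSeries:
    """Per-interval uptake/decay rate coefficients.

    ``order`` 1 carries units of min⁻¹; order 2 carries
    L·mmol⁻¹·min⁻¹.  One entry per consecutive pair of samples, reported
    at the interval's right endpoint (matching the row layout of the
    rate tables this convention reconstructs).
    """

    order: int
    intervals: tuple[RateInterval, ...]

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValidationError("order must be 1 or 2")

    @property
    def units(self) -> str:
        return "min^-1" if self.order == 1 else "L.mmol^-1.min^-1"

    @property
    def values(self) -> np.ndarray:
        return np.array([iv.value for iv in self.intervals], dtype=float)

    @property
    def end_times(self) -> np.ndarray:
        return np.array([iv.t_end for iv in self.intervals], dtype=float)

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval_start": [iv.t_start for iv in self.intervals],
                "time_min": self.end_times,
                "order": self.order,
                "k_value": self.values,
                "units": self.units,
            }
        )


def fit_first_order_rates(tc: UptakeTimeCourse) -> RateCoefficientSeries:
    """Per-interval first-order uptake coefficients k₁ (min⁻¹).

    k₁ for the interval (tᵢ₋₁, tᵢ] is the uptake increment per minute
    normalised by the initial total extracellular concentration:
    (Uᵢ − Uᵢ₋₁)/((tᵢ − tᵢ₋₁)·C₀).  Negative entries flag the
    intracellular decay phase.
    """
    if len(tc.points) < 2:
        raise InsufficientDataError("need at least 2 points to form an interval")
    t = tc.times
    u = tc.uptake
    k = np.diff(u) / (np.diff(t) * tc.C0_uM)
    intervals = tuple(
        RateInterval(float(t[i]), float(t[i + 1]), float(k[i]))
        for i in range(len(k))
    )
    return RateCoefficientSeries(order=1, intervals=intervals)


def fit_second_order_rates(tc: UptakeTimeCourse) -> RateCoefficientSeries:
    """Per-interval second-order coefficients k₂ (L·mmol⁻¹·min⁻¹).

    k₂ = k₁ / S_nM with the carrier dose S expressed in nM
    (S_mM × 10⁶); see the module docstring for why the nM expression is
    used.
    """
    if not tc.has_carrier:
        raise CarrierRequiredError(
            "second-order coefficients require carrier_dose_mM > 0"
        )
    k1 = fit_first_order_rates(tc)
    s_nM = tc.carrier_dose_mM * _MM_TO_NM
    intervals = tuple(
        replace(iv, value=iv.value / s_nM) for iv in k1.intervals
    )
    return RateCoefficientSeries(order=2, intervals=intervals)


def detect_peak(tc: UptakeTimeCourse) -> tuple[float, float]:
    """Time and value of the uptake maximum; ties break to the earliest time."""
    if len(tc.points) < 2:
        raise InsufficientDataError("need at least 2 points to locate a peak")
    u = tc.uptake
    i = int(np.argmax(u))  # argmax returns the first maximum
    return float(tc.times[i]), float(u[i])


def decay_phase_rates(tc: UptakeTimeCourse) -> RateCoefficientSeries:
    """Rate coefficients for the post-peak intracellular decay phase only.

    The coefficient order follows the carrier context (second order with
    carrier, first order without).  If the peak falls on the last sample
    an empty series is returned with a warning.
    """
    t_peak, _ = detect_peak(tc)
    series = (
        fit_second_order_rates(tc) if tc.has_carrier else fit_first_order_rates(tc)
    )
    post = tuple(iv for iv in series.intervals if iv.t_start >= t_peak)
    if not post:
        warnings.warn("no post-peak interval: series is monotone to the last point")
    return RateCoefficientSeries(order=series.order, intervals=post)


def simulate_uptake_curve(
    k: float,
    *,
    order: int = 1,
    C0_uM: float,
    carrier_conc: float = 0.0,
    U0_uM: float = 0.0,
    elimination_rate: float = 0.0,
    times: Sequence[float],
) -> UptakeTimeCourse:
    """Forward-simulate an uptake curve from a single rate coefficient.

    The extracellular pool decays as dC/dt = −k·C (order 1) or
    dC/dt = −k·S·C with constant carrier concentration S (order 2, which
    reduces to order 1 with effective rate k·S).  Intracellular uptake is
    U = U₀ + (C₀ − C) less first-order elimination at rate ``elimination_rate``:

        dU/dt = k_eff·C − k_e·U,   U(0) = U₀.

    The closed-form solution is evaluated exactly, so the output is
    noiseless and deterministic.  ``carrier_conc`` must be expressed in
    units that make k·S a frequency (min⁻¹); with k in L·mmol⁻¹·min⁻¹
    that is the nM reading of the dose used throughout this module.
    """
    if C0_uM < 0:
        raise ValidationError("C0_uM must be non-negative")
    if k < 0:
        raise ValidationError("forward simulation requires k >= 0")
    if order not in (1, 2):
        raise ValidationError("order must be 1 or 2")
    k_eff = k if order == 1 else k * carrier_conc
    t = np.asarray(times, dtype=float)
    u = _uptake_closed_form(t, k_eff, C0_uM, U0_uM, elimination_rate)
    with warnings.catch_warnings():
        # the U0 offset sits on top of the transferable pool here, so the
        # simulated uptake may legitimately approach C0 + U0
        warnings.simplefilter("ignore")
        return UptakeTimeCourse.from_arrays(
            "simulated",
            t,
            np.clip(u, 0.0, None),
            C0_uM=max(C0_uM, np.finfo(float).tiny),
            carrier_dose_mM=0.0,
        )


def _uptake_closed_form(
    t: np.ndarray, k: float, C0: float, U0: float, ke: float
) -> np.ndarray:
    """Exact solution of dU/dt = k·C₀·e^{−kt} − ke·U, U(0)=U0."""
    if ke == 0.0:
        return U0 + C0 * (1.0 - np.exp(-k * t))
    if k == 0.0:
        return U0 * np.exp(-ke * t)
    if np.isclose(k, ke, rtol=1e-12, atol=0.0):
        return (U0 + k * C0 * t) * np.exp(-k * t)
    return U0 * np.exp(-ke * t) + (
        k * C0 * (np.exp(-k * t) - np.exp(-ke * t)) / (ke - k)
    )


class UptakeKinetics:
    """Interval-rate kinetic model for one uptake time course.

    Thin estimation wrapper in the model/results idiom: construct from an
    :class:`UptakeTimeCourse` (or a tidy DataFrame), call :meth:`fit`, and
    read the per-interval coefficients, the peak and the decay phase off
    the returned :class:`UptakeKineticsResults`.
    """

    def __init__(self, timecourse: UptakeTimeCourse):
        self.timecourse = timecourse

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        lignan: str | None = None,
        C0_uM: float,
        carrier_dose_mM: float | None = None,
    ) -> "UptakeKinetics":
        """Build from a tidy frame with ``time_min``/``uptake_uM`` columns."""
        sub = df
        if lignan is not None and "lignan" in df.columns:
            sub = df[df["lignan"] == lignan]
        if lignan is None:
            lignan = str(sub["lignan"].iloc[0]) if "lignan" in sub.columns else "?"
        if carrier_dose_mM is None:
            carrier_dose_mM = (
                float(sub["carrier_dose_mM"].iloc[0])
                if "carrier_dose_mM" in sub.columns
                else 0.0
            )
        sub = sub.sort_values("time_min")
        tc = UptakeTimeCourse.from_arrays(
            lignan,
            sub["time_min"].to_numpy(),
            sub["uptake_uM"].to_numpy(),
            C0_uM=C0_uM,
            carrier_dose_mM=carrier_dose_mM,
            sd=sub["sd_uM"].to_numpy() if "sd_uM" in sub.columns else None,
            extrapolated=(
                sub["extrapolated"].to_numpy()
                if "extrapolated" in sub.columns
                else None
            ),
        )
        return cls(tc)

    def fit(self) -> "UptakeKineticsResults":
        tc = self.timecourse
        first = fit_first_order_rates(tc)
        second = fit_second_order_rates(tc) if tc.has_carrier else None
        t_peak, u_peak = detect_peak(tc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            decay = decay_phase_rates(tc)
        return UptakeKineticsResults(
            model=self,
            first_order=first,
            second_order=second,
            peak_time_min=t_peak,
            peak_uptake_uM=u_peak,
            decay_phase=decay,
        )


@dataclass(frozen=True)
class UptakeKineticsResults:
    """Fitted per-interval coefficients and derived kinetic quantities."""

    model: UptakeKinetics
    first_order: RateCoefficientSeries
    second_order: RateCoefficientSeries | None
    peak_time_min: float
    peak_uptake_uM: float
    decay_phase: RateCoefficientSeries
    extra: dict = field(default_factory=dict)

    @property
    def rates(self) -> RateCoefficientSeries:
        """The series matching the carrier context of the input."""
        return self.second_order if self.second_order is not None else self.first_order

    def to_frame(self) -> pd.DataFrame:
        frames = [self.first_order.to_frame()]
        if self.second_order is not None:
            frames.append(self.second_order.to_frame())
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        tc = self.model.timecourse
        lines = [
            "Uptake kinetics (interval rate coefficients)",
            "=" * 52,
            f"lignan:            {tc.lignan}",
            f"carrier dose:      {tc.carrier_dose_mM:g} mM",
            f"C0:                {tc.C0_uM:g} uM",
            f"peak:              {self.peak_uptake_uM:g} uM at {self.peak_time_min:g} min",
            f"decay intervals:   {len(self.decay_phase)}",
            "-" * 52,
        ]
        lines.append(self.to_frame().to_string(index=False))
        return "\n".join(lines)
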