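"""Pharmacodynamic statistics for viability dose-response curves.

Two statistics summarise each MTT-style viability curve:

* **IC50** — the dose giving 50% viability relative to the untreated
  control, estimated either by a four-parameter logistic (4PL) fit or by
  monotone interpolation to the 50% crossing.
* **Killing capability** — cells killed per mM of compound: the
  ordinary-least-squares slope of the absolute killed-cell count
  ``(1 − viability/100) · seeded_cells`` against dose, taken over a
  user-declared linearity range of the curve.

Viability above 100% (low-dose proliferative "hormesis") is legal data;
such points contribute negative killed counts and are normally excluded
by declaring a linearity range that starts above them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import SEEDED_CELLS
from .errors import (
    ComparisonError,
    InsufficientRangeError,
    NoCrossingError,
    ValidationError,
)

__all__ = [
    "DoseResponsePoint",
    "DoseResponseCurve",
    "PDSummary",
    "four_param_logistic",
    "estimate_ic50",
    "killing_capability",
    "compare_pd",
    "DoseResponseModel",
    "DoseResponseResults",
]


def four_param_logistic(
    dose: np.ndarray | float,
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
) -> np.ndarray | float:
    """Descending 4PL: viability = bottom + (top−bottom)/(1+(d/ic50)^hill).

    At d = ic50 the viability is the midpoint (top+bottom)/2, so for
    top = 100, bottom = 0 the inflection dose is the IC50 proper.
    """
    d = np.asarray(dose, dtype=float)
    v = bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)
    return v if np.ndim(dose) else float(v)


@dataclass(frozen=True)
class DoseResponsePoint:
    dose_mM: float
    viability_pct: float
    sd_pct: float | None = None


@dataclass(frozen=True)
class DoseResponseCurve:
    """Viability (% of untreated control) versus dose for one treatment.

    ``carrier`` distinguishes the lignan+carrier combination from the
    free lignan; the control (dose → 0) viability is 100 by definition.
    """

    compound: str
    carrier: bool
    incubation_h: float
    points: tuple[DoseResponsePoint, ...]
    seeded_cells: float = SEEDED_CELLS

    def __post_init__(self) -> None:
        doses = self.doses
        if len(doses) and doses[0] < 0:
            raise ValidationError("doses must be non-negative")
        if len(doses) > 1 and not np.all(np.diff(doses) > 0):
            raise ValidationError("doses must be strictly increasing")
        if any(p.viability_pct < 0 for p in self.points):
            raise ValidationError("viability must be non-negative")
        if self.seeded_cells <= 0:
            raise ValidationError("seeded_cells must be positive")

    @classmethod
    def from_arrays(
        cls,
        compound: str,
        doses: Sequence[float],
        viability: Sequence[float],
        *,
        carrier: bool = False,
        incubation_h: float = 48.0,
        sd: Sequence[float] | None = None,
        seeded_cells: float = SEEDED_CELLS,
    ) -> "DoseResponseCurve":
        if len(doses) != len(viability):
            raise ValidationError("doses and viability must have equal length")
        sds: list[float | None] = list(sd) if sd is not None else [None] * len(doses)
        pts = tuple(
            DoseResponsePoint(float(d), float(v), None if s is None else float(s))
            for d, v, s in zip(doses, viability, sds)
        )
        return cls(compound, carrier, float(incubation_h), pts, float(seeded_cells))

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose_mM for p in self.points], dtype=float)

    @property
    def viability(self) -> np.ndarray:
        return np.array([p.viability_pct for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "carrier": self.carrier,
                "dose_mM": self.doses,
                "viability_pct": self.viability,
                "incubation_h": self.incubation_h,
            }
        )


@dataclass(frozen=True)
class PDSummary:
    """IC50 and killing-capability summary for one treatment."""

    compound: str
    carrier: bool
    incubation_h: float
    ic50_mM: float
    ic50_method: str
    killing_capability: float | None = None  # cells per mM
    linearity_range: tuple[float, float] | None = None
    ic50_ci: tuple[float, float] | None = None
    extrapolated: bool = False


def _fit_4pl(doses: np.ndarray, viability: np.ndarray) -> tuple[float, float, float, float]:
    top0 = float(viability.max())
    bottom0 = float(min(viability.min(), 0.0))
    # initial IC50: dose nearest the 50% level, clipped into the dose span
    i = int(np.argmin(np.abs(viability - 50.0)))
    ic0 = float(np.clip(doses[i], doses[doses > 0].min(), doses.max()))
    p0 = (top0, bottom0, ic0, 1.0)
    bounds = ([0.0, -50.0, 1e-12, 0.05], [500.0, 100.0, 1e6, 20.0])
    popt, _ = optimize.curve_fit(
        four_param_logistic, doses, viability, p0=p0, bounds=bounds, maxfev=20000
    )
    return tuple(float(x) for x in popt)  # type: ignore[return-value]


def _interp_ic50(
    doses: np.ndarray,
    viability: np.ndarray,
    *,
    scale: str = "log",
    allow_extrapolation: bool = False,
) -> tuple[float, bool]:
    above = viability > 50.0
    if above.all() or (~above).all():
        if not allow_extrapolation:
            raise NoCrossingError(
                "viability never crosses 50%; pass allow_extrapolation=True "
                "to extrapolate from the terminal segment"
            )
        i0, i1 = (len(doses) - 2, len(doses) - 1) if above.all() else (0, 1)
        extrapolated = True
    else:
        # first index where the curve has crossed 50 going down
        idx = int(np.argmax(~above)) if above[0] else int(np.argmax(above))
        i0, i1 = idx - 1, idx
        extrapolated = False
    d0, d1 = doses[i0], doses[i1]
    v0, v1 = viability[i0], viability[i1]
    if v0 == v1:
        raise NoCrossingError("flat segment at the 50% level; IC50 undefined")
    if scale == "log":
        if d0 <= 0:
            scale = "linear"  # cannot take log of a zero dose
    if scale == "log":
        x0, x1 = np.log(d0), np.log(d1)
        x = x0 + (50.0 - v0) * (x1 - x0) / (v1 - v0)
        return float(np.exp(x)), extrapolated
    x = d0 + (50.0 - v0) * (d1 - d0) / (v1 - v0)
    return float(x), extrapolated


def estimate_ic50(
    curve: DoseResponseCurve,
    method: str = "4pl",
    *,
    scale: str = "log",
    allow_extrapolation: bool = False,
) -> float:
    """Estimate the IC50 (mM) of a viability curve.

    ``method`` is ``"4pl"`` (least-squares four-parameter logistic; the
    IC50 is the inflection dose) or ``"interp"`` (piecewise-linear
    interpolation to the 50% crossing, on ``scale`` = ``"log"`` dose by
    default or ``"linear"``).  The default 4PL falls back to
    interpolation if the optimiser fails to converge.
    """
    doses, viability = curve.doses, curve.viability
    if method == "4pl":
        try:
            _, _, ic50, _ = _fit_4pl(doses, viability)
            return ic50
        except (RuntimeError, ValueError):
            method = "interp"  # fall through to the robust estimator
    if method == "interp":
        ic50, _ = _interp_ic50(
            doses, viability, scale=scale, allow_extrapolation=allow_extrapolation
        )
        return ic50
    raise ValidationError(f"unknown IC50 method {method!r}")


def killing_capability(
    curve: DoseResponseCurve,
    linearity_range: tuple[float, float],
    *,
    seeded_cells: float | None = None,
) -> float:
    """Cells killed per mM over the declared linearity range.

    The killed-cell count at dose d is (1 − viability(d)/100) × seeded
    cells; the statistic is the OLS slope of killed count versus dose for
    the points with dose in the half-open interval (lo, hi].
    """
    lo, hi = linearity_range
    if hi <= lo:
        raise ValidationError("linearity range must satisfy lo < hi")
    seeded = curve.seeded_cells if seeded_cells is None else float(seeded_cells)
    mask = (curve.doses > lo) & (curve.doses <= hi)
    if mask.sum() < 2:
        raise InsufficientRangeError(
            f"need >=2 points in ({lo}, {hi}]; found {int(mask.sum())}"
        )
    d = curve.doses[mask]
    killed = (1.0 - curve.viability[mask] / 100.0) * seeded
    res = stats.linregress(d, killed)
    return float(res.slope)


@dataclass(frozen=True)
class PDComparison:
    compound: str
    incubation_h: float
    delta_ic50_mM: float
    killing_fold_change: float | None
    label: str


def compare_pd(
    free: PDSummary, combined: PDSummary, *, rel_tol: float = 0.01
) -> PDComparison:
    """Compare free-lignan and lignan+carrier pharmacodynamics.

    Returns ΔIC50 = IC50(free) − IC50(combined) (positive when the
    carrier lowers the IC50), the killing-capability fold change
    (combined/free), and a direction label decided on the IC50 with a 1%
    relative tolerance: ``enhanced`` (combined IC50 lower),
    ``attenuated`` (higher) or ``unchanged``.
    """
    if free.compound != combined.compound:
        raise ComparisonError(
            f"cannot compare {free.compound!r} with {combined.compound!r}"
        )
    if free.incubation_h != combined.incubation_h:
        raise ComparisonError("incubation times differ")
    delta = free.ic50_mM - combined.ic50_mM
    fold = None
    if free.killing_capability and combined.killing_capability is not None:
        fold = combined.killing_capability / free.killing_capability
    if combined.ic50_mM < free.ic50_mM * (1.0 - rel_tol):
        label = "enhanced"
    elif combined.ic50_mM > free.ic50_mM * (1.0 + rel_tol):
        label = "attenuated"
    else:
        label = "unchanged"
    return PDComparison(free.compound, free.incubation_h, delta, fold, label)


class DoseResponseModel:
    """Dose-response model for one viability curve.

    ``fit`` estimates the IC50 (4PL by default, with interpolation
    fallback) and, when a linearity range is declared, the killing
    capability; ``DoseResponseResults.bootstrap_ic50`` resamples
    replicate noise for a confidence interval.
    """

    def __init__(self, curve: DoseResponseCurve):
        self.curve = curve

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        compound: str | None = None,
        carrier: bool | None = None,
        incubation_h: float | None = None,
        seeded_cells: float = SEEDED_CELLS,
    ) -> "DoseResponseModel":
        sub = df
        if compound is not None:
            sub = sub[sub["compound"] == compound]
        if carrier is not None and "carrier" in sub.columns:
            sub = sub[sub["carrier"].astype(bool) == carrier]
        if incubation_h is not None and "incubation_h" in sub.columns:
            sub = sub[sub["incubation_h"] == incubation_h]
        if not len(sub):
            raise ValidationError("no rows match the requested treatment")
        sub = sub.sort_values("dose_mM")
        curve = DoseResponseCurve.from_arrays(
            compound or str(sub["compound"].iloc[0]),
            sub["dose_mM"].to_numpy(),
            sub["viability_pct"].to_numpy(),
            carrier=bool(sub["carrier"].iloc[0]) if "carrier" in sub.columns else False,
            incubation_h=(
                float(sub["incubation_h"].iloc[0])
                if "incubation_h" in sub.columns
                else 48.0
            ),
            seeded_cells=seeded_cells,
        )
        return cls(curve)

    def fit(
        self,
        *,
        ic50_method: str = "4pl",
        linearity_range: tuple[float, float] | None = None,
        allow_extrapolation: bool = False,
    ) -> "DoseResponseResults":
        curve = self.curve
        params = None
        method_used = ic50_method
        if ic50_method == "4pl":
            try:
                params = _fit_4pl(curve.doses, curve.viability)
                ic50 = params[2]
                extrapolated = not (
                    curve.doses.min() <= ic50 <= curve.doses.max()
                )
            except (RuntimeError, ValueError):
                method_used = "interp"
        if method_used == "interp":
            ic50, extrapolated = _interp_ic50(
                curve.doses,
                curve.viability,
                allow_extrapolation=allow_extrapolation,
            )
        elif method_used not in ("4pl", "interp"):
            raise ValidationError(f"unknown IC50 method {method_used!r}")
        kc = (
            killing_capability(curve, linearity_range)
            if linearity_range is not None
            else None
        )
        return DoseResponseResults(
            model=self,
            ic50_mM=ic50,
            ic50_method=method_used,
            params_4pl=params,
            killing_capability_=kc,
            linearity_range=linearity_range,
            extrapolated=extrapolated,
        )


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted pharmacodynamic statistics for one treatment."""

    model: DoseResponseModel
    ic50_mM: float
    ic50_method: str
    params_4pl: tuple[float, float, float, float] | None
    killing_capability_: float | None
    linearity_range: tuple[float, float] | None
    extrapolated: bool
    extra: dict = field(default_factory=dict)

    @property
    def curve(self) -> DoseResponseCurve:
        return self.model.curve

    def predict(self, dose):
        """Predicted viability at ``dose`` from the fitted 4PL."""
        if self.params_4pl is None:
            raise ValidationError("no 4PL parameters; fit used interpolation")
        return four_param_logistic(dose, *self.params_4pl)

    def bootstrap_ic50(
        self, n_boot: int = 1000, *, seed: int | None = None, noise_sd: float | None = None
    ) -> tuple[float, float]:
        """Percentile 95% CI for the IC50 by resampling replicate noise.

        Per-point Gaussian noise uses the recorded replicate SDs where
        present, else ``noise_sd``, else the RMS residual of the 4PL fit.
        """
        curve = self.curve
        rng = np.random.default_rng(seed)
        sds = np.array(
            [p.sd_pct if p.sd_pct is not None else np.nan for p in curve.points]
        )
        if np.isnan(sds).any():
            if noise_sd is not None:
                fill = noise_sd
            elif self.params_4pl is not None:
                resid = curve.viability - np.asarray(self.predict(curve.doses))
                fill = float(np.sqrt(np.mean(resid**2)))
            else:
                raise ValidationError(
                    "no replicate SDs and no noise_sd given for the bootstrap"
                )
            sds = np.where(np.isnan(sds), fill, sds)
        estimates = []
        for _ in range(n_boot):
            vib = np.clip(curve.viability + rng.normal(0.0, sds), 0.0, None)
            try:
                boot = DoseResponseCurve.from_arrays(
                    curve.compound,
                    curve.doses,
                    vib,
                    carrier=curve.carrier,
                    incubation_h=curve.incubation_h,
                    seeded_cells=curve.seeded_cells,
                )
                estimates.append(
                    estimate_ic50(boot, self.ic50_method, allow_extrapolation=True)
                )
            except (NoCrossingError, RuntimeError):
                continue
        if len(estimates) < max(10, n_boot // 10):
            raise ValidationError("bootstrap failed on too many resamples")
        lo, hi = np.percentile(estimates, [2.5, 97.5])
        return float(lo), float(hi)

    def pd_summary(self) -> PDSummary:
        curve = self.curve
        return PDSummary(
            compound=curve.compound,
            carrier=curve.carrier,
            incubation_h=curve.incubation_h,
            ic50_mM=self.ic50_mM,
            ic50_method=self.ic50_method,
            killing_capability=self.killing_capability_,
            linearity_range=self.linearity_range,
            extrapolated=self.extrapolated,
        )

    def summary(self) -> str:
        curve = self.curve
        kc = (
            f"{self.killing_capability_:.4g} cells/mM over "
            f"({self.linearity_range[0]:g}, {self.linearity_range[1]:g}] mM"
            if self.killing_capability_ is not None
            else "not computed (no linearity range declared)"
        )
        lines = [
            "Dose-response summary",
            "=" * 52,
            f"compound:            {curve.compound}"
            + (" + carrier" if curve.carrier else " (free)"),
            f"incubation:          {curve.incubation_h:g} h",
            f"doses:               {len(curve.points)} "
            f"({curve.doses.min():g}-{curve.doses.max():g} mM)",
            f"IC50:                {self.ic50_mM:.4g} mM  [{self.ic50_method}]"
            + ("  (extrapolated)" if self.extrapolated else ""),
            f"killing capability:  {kc}",
        ]
        if self.params_4pl is not None:
            top, bottom, ic50, hill = self.params_4pl
            lines.append(
                f"4PL params:          top={top:.3g} bottom={bottom:.3g} "
                f"ic50={ic50:.4g} hill={hill:.3g}"
            )
        return "\n".join(lines)
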