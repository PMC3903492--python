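"""Typed CSV/JSON input and output.

CSV schemas (UTF-8, comma, header):

* uptake — ``lignan,carrier_dose_mM,time_min,uptake_uM,sd_uM,extrapolated``
  (optional ``C0_uM`` column; otherwise supply it at read time);
* dose-response — ``compound,carrier,dose_mM,viability_pct,incubation_h``
  (optional ``sd_pct``).

Rows are sorted into canonical order (compound, carrier, time or dose)
on load, so shuffled files parse to the same objects, and write∘read is
the identity on values and flags.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import C0_UM
from .doseresponse import DoseResponseCurve
from .errors import SchemaError
from .kinetics import UptakeTimeCourse
from .thermo import FreeEnergyLedger

__all__ = [
    "read_uptake_csv",
    "write_uptake_csv",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "write_ledger_json",
    "read_ledger_json",
]

_UPTAKE_COLS = ("lignan", "carrier_dose_mM", "time_min", "uptake_uM")
_DR_COLS = ("compound", "carrier", "dose_mM", "viability_pct", "incubation_h")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-numeric value in column {c!r}: {exc}")
    return df


def read_uptake_csv(path, *, C0_uM: float = C0_UM) -> list[UptakeTimeCourse]:
    """Read uptake time courses, one per (lignan, carrier dose) group."""
    df = pd.read_csv(path)
    _require_columns(df, _UPTAKE_COLS, path)
    df = _numeric(df, ["carrier_dose_mM", "time_min", "uptake_uM"], path)
    if "sd_uM" in df.columns:
        df["sd_uM"] = pd.to_numeric(df["sd_uM"], errors="coerce")
    if "C0_uM" in df.columns:
        df = _numeric(df, ["C0_uM"], path)
    out = []
    for (lignan, dose), sub in df.groupby(["lignan", "carrier_dose_mM"], sort=True):
        sub = sub.sort_values("time_min")
        sds = (
            [None if pd.isna(s) else float(s) for s in sub["sd_uM"]]
            if "sd_uM" in sub.columns
            else None
        )
        flags = (
            sub["extrapolated"]
            .map(lambda x: str(x).strip().lower() in ("true", "1", "yes"))
            .tolist()
            if "extrapolated" in sub.columns
            else None
        )
        c0 = float(sub["C0_uM"].iloc[0]) if "C0_uM" in sub.columns else C0_uM
        out.append(
            UptakeTimeCourse.from_arrays(
                str(lignan),
                sub["time_min"].to_numpy(),
                sub["uptake_uM"].to_numpy(),
                C0_uM=c0,
                carrier_dose_mM=float(dose),
                sd=sds,
                extrapolated=flags,
            )
        )
    return out


def write_uptake_csv(timecourses: Iterable[UptakeTimeCourse], path) -> None:
    frames = []
    for tc in timecourses:
        df = tc.to_frame()
        df["C0_uM"] = tc.C0_uM
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["lignan", "carrier_dose_mM", "time_min"])
    out.to_csv(path, index=False)


def read_dose_response_csv(path) -> list[DoseResponseCurve]:
    """Read viability curves, one per (compound, carrier, incubation) group."""
    df = pd.read_csv(path)
    _require_columns(df, _DR_COLS, path)
    df = _numeric(df, ["dose_mM", "viability_pct", "incubation_h"], path)
    df["carrier"] = df["carrier"].map(
        lambda x: str(x).strip().lower() in ("true", "1", "yes")
    )
    out = []
    keys = ["compound", "carrier", "incubation_h"]
    for (compound, carrier, hours), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("dose_mM")
        sds = None
        if "sd_pct" in sub.columns:
            vals = pd.to_numeric(sub["sd_pct"], errors="coerce")
            sds = [None if pd.isna(s) else float(s) for s in vals]
        out.append(
            DoseResponseCurve.from_arrays(
                str(compound),
                sub["dose_mM"].to_numpy(),
                sub["viability_pct"].to_numpy(),
                carrier=bool(carrier),
                incubation_h=float(hours),
                sd=sds,
            )
        )
    return out


def write_dose_response_csv(curves: Iterable[DoseResponseCurve], path) -> None:
    frames = []
    for c in curves:
        df = c.to_frame()
        df["sd_pct"] = [p.sd_pct if p.sd_pct is not None else np.nan for p in c.points]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["compound", "carrier", "dose_mM"])
    out.to_csv(path, index=False)


def write_ledger_json(ledgers: Iterable[FreeEnergyLedger], path) -> None:
    """Serialise ledgers; ±∞ becomes the strings "+inf"/"-inf"."""
    payload = [ledger.to_dict() for ledger in ledgers]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_ledger_json(path) -> list[dict]:
    """Read a ledger JSON back into plain dicts with float ±inf restored."""

    def _restore(x):
        if x == "+inf":
            return float("inf")
        if x == "-inf":
            return float("-inf")
        return x

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    for ledger in payload:
        ledger["overall_J"] = _restore(ledger["overall_J"])
        for step in ledger["steps"]:
            step["keq"] = _restore(step["keq"])
            step["delta_g_J"] = _restore(step["delta_g_J"])
    return payload
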