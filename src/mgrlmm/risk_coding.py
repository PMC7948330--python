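"""ATP-III three-category coding of the eight cardiovascular risk factors.

Each continuous measurement is mapped to an ordered code — 0 normal,
1 borderline, 2 impaired — using the Adult Treatment Panel III bands.  HDL-C
and hs-CRP are reverse-oriented (high HDL is healthy, low hs-CRP is healthy);
waist circumference bands are sex-specific; blood pressure combines the
systolic and diastolic bands by elementwise maximum, the standard staging
rule.  The fixed indicator order used throughout the package is
(BMI, TG, BP, LDL, FBG, HDL, WC, hsCRP).

Boundary conventions honour every printed inequality: bands written
"a to b" with the impaired band opening at "≥ b" use lower-inclusive /
upper-exclusive borderline intervals, while bands whose impaired band opens
at "> b" keep b itself borderline (WC, hs-CRP, HDL at 40/60).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_NAMES",
    "RiskFactorPanel",
    "code_panel",
    "code_frame",
    "count_impaired",
    "cutoff_table",
]

#: Fixed ordinal-indicator order used by the measurement model.
ITEM_NAMES: tuple[str, ...] = ("bmi", "tg", "bp", "ldl", "fbg", "hdl", "wc", "hscrp")

# (lower cut, upper cut, lower-band comparison, upper-band comparison)
# code 0 while value `lo_op` lower-cut; code 2 once value `hi_op` upper-cut.
_DIRECT_BANDS: dict[str, tuple[float, float, str, str]] = {
    "bmi": (25.0, 30.0, "<", ">="),
    "tg": (150.0, 200.0, "<", ">="),
    "ldl": (130.0, 160.0, "<", ">="),
    "fbg": (110.0, 126.0, "<", ">="),
    "hscrp": (1.0, 3.0, "<", ">"),
}
_WC_BANDS = {"female": (80.0, 88.0, "<", ">"), "male": (94.0, 102.0, "<", ">")}
# systolic / diastolic components of the joint BP rule ("≤120/80 normal,
# ≥140/90 impaired"): normal is value ≤ lower cut, impaired value ≥ upper cut.
_SBP = (120.0, 140.0, "<=", ">=")
_DBP = (80.0, 90.0, "<=", ">=")
# HDL is reverse-oriented: > 60 normal, 40–60 borderline, < 40 impaired.
_HDL = (60.0, 40.0)


def _band_code(value: float, lo: float, hi: float, lo_op: str, hi_op: str) -> int:
    low = value < lo if lo_op == "<" else value <= lo
    if low:
        return 0
    high = value >= hi if hi_op == ">=" else value > hi
    return 2 if high else 1


@dataclass(frozen=True)
class RiskFactorPanel:
    """One subject-wave set of raw measurements (``None``/NaN = missing)."""

    sbp: float | None = None
    dbp: float | None = None
    bmi: float | None = None
    wc: float | None = None
    fbg: float | None = None
    tg: float | None = None
    ldl: float | None = None
    hdl: float | None = None
    hscrp: float | None = None
    sex: str | None = None


def _missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def code_panel(panel: RiskFactorPanel) -> dict[str, int | None]:
    """Code one panel into the eight ordered indicators.

    Returns a dict keyed by :data:`ITEM_NAMES` with values in {0, 1, 2} or
    ``None`` where the measurement is missing.  Waist circumference requires
    ``sex``; blood pressure is the max of the SBP and DBP band codes and is
    missing if either component is missing.
    """
    out: dict[str, int | None] = {}

    for item in ("bmi", "tg", "ldl", "fbg", "hscrp"):
        value = getattr(panel, item)
        if _missing(value):
            out[item] = None
        else:
            if value < 0:
                raise ValueError(f"{item} must be non-negative, got {value}")
            out[item] = _band_code(float(value), *_DIRECT_BANDS[item])

    if _missing(panel.sbp) or _missing(panel.dbp):
        out["bp"] = None
    else:
        out["bp"] = max(
            _band_code(float(panel.sbp), *_SBP), _band_code(float(panel.dbp), *_DBP)
        )

    if _missing(panel.hdl):
        out["hdl"] = None
    else:
        hi, lo = _HDL
        out["hdl"] = 0 if panel.hdl > hi else (2 if panel.hdl < lo else 1)

    if _missing(panel.wc):
        out["wc"] = None
    else:
        if panel.sex not in _WC_BANDS:
            raise ValueError(
                "sex must be 'female' or 'male' when waist circumference is present"
            )
        out["wc"] = _band_code(float(panel.wc), *_WC_BANDS[panel.sex])

    return {item: out[item] for item in ITEM_NAMES}


def code_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Code raw measurement columns of a cohort frame into ``item_*`` columns.

    Expects columns named as in :class:`RiskFactorPanel` plus ``sex``; returns
    a copy with nullable-integer columns ``item_bmi`` … ``item_hscrp``
    appended, ready for the measurement model.
    """
    coded = {f"item_{name}": [] for name in ITEM_NAMES}
    for row in df.itertuples(index=False):
        panel = RiskFactorPanel(
            sbp=getattr(row, "sbp", None),
            dbp=getattr(row, "dbp", None),
            bmi=getattr(row, "bmi", None),
            wc=getattr(row, "wc", None),
            fbg=getattr(row, "fbg", None),
            tg=getattr(row, "tg", None),
            ldl=getattr(row, "ldl", None),
            hdl=getattr(row, "hdl", None),
            hscrp=getattr(row, "hscrp", None),
            sex=getattr(row, "sex", None),
        )
        codes = code_panel(panel)
        for name in ITEM_NAMES:
            coded[f"item_{name}"].append(codes[name])
    out = df.copy()
    for col, vals in coded.items():
        out[col] = pd.array(vals, dtype="Int64")
    return out


def count_impaired(codes: Iterable[int]) -> int:
    """Number of indicators at the impaired level (code 2) out of eight.

    All eight codes must be present; the caller decides how to handle
    missingness before counting.
    """
    arr = list(codes)
    if len(arr) != 8:
        raise ValueError(f"expected 8 codes, got {len(arr)}")
    for c in arr:
        if c is None or (isinstance(c, float) and math.isnan(c)):
            raise ValueError("missing code; impute or exclude before counting")
        if c not in (0, 1, 2):
            raise ValueError(f"code {c!r} outside {{0,1,2}}")
    return int(sum(1 for c in arr if c == 2))


def cutoff_table() -> pd.DataFrame:
    """The coding bands as one auditable table (for display / the CLI)."""
    rows = [
        ("bmi", "kg/m^2", "< 25", "25 to < 30", ">= 30"),
        ("tg", "mg/dl", "< 150", "150 to < 200", ">= 200"),
        ("bp", "mmHg", "<= 120/80", "120/80 to 140/90", ">= 140/90"),
        ("ldl", "mg/dl", "< 130", "130 to < 160", ">= 160"),
        ("fbg", "mg/dl", "< 110", "110 to < 126", ">= 126"),
        ("hdl", "mg/dl", "> 60", "40 to 60", "< 40"),
        ("wc", "cm", "F < 80 / M < 94", "F 80-88 / M 94-102", "F > 88 / M > 102"),
        ("hscrp", "mg/l", "< 1", "1 to 3", "> 3"),
    ]
    return pd.DataFrame(rows, columns=["item", "units", "normal", "borderline", "impaired"])
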