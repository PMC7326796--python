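"""Derived nanostructure metrics and study-level report tables.

Elementary-fibril (EF) spacing comes from the diffraction-peak position as
d = 2*pi/q0, converted to nanometres.  Reports collect, per sample, the low-q
exponent P1 and EF spacing from the two-level fit of the subtracted curve and
the mid-q Rg and P2 from the three-level fit of the amorphous/isotropic curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .fitting import FitResult, ParameterInterval

__all__ = [
    "ef_spacing_nm",
    "ef_spacing_interval_nm",
    "relative_change_pct",
    "classify_q_region",
    "ReportRow",
    "compile_report",
    "report_to_text",
]

TREATMENT_COLUMNS = ("delignification", "cmf_pulses", "decay_days", "enzyme")


def ef_spacing_nm(q0: float) -> float:
    """Elementary-fibril spacing d = 2*pi/q0, returned in nm for q0 in A^-1."""
    if q0 <= 0:
        raise DomainError("q0 must be > 0")
    return (2.0 * np.pi / q0) / 10.0


def ef_spacing_interval_nm(q0_interval) -> tuple:
    """Map a (lo, hi) q0 interval through the (monotone decreasing) spacing."""
    lo, hi = q0_interval
    return (ef_spacing_nm(hi), ef_spacing_nm(lo))


def relative_change_pct(reference: float, treated: float) -> float:
    """Percent change of ``treated`` relative to ``reference``."""
    if reference <= 0:
        raise DomainError("reference value must be > 0")
    return 100.0 * (treated - reference) / reference


# q-region boundaries in A^-1: half-open [lo, hi) except high-q closed at 0.3
_REGIONS = (("low", 0.001, 0.01), ("mid", 0.01, 0.1), ("high", 0.1, 0.3))


def classify_q_region(q: float) -> str:
    if q < 0:
        raise DomainError("q must be >= 0")
    for name, lo, hi in _REGIONS:
        if lo <= q < hi:
            return name
    if q == 0.3:
        return "high"
    return "out_of_range"


@dataclass
class ReportRow:
    """One table row: a sample's fitted nanostructure metrics."""

    sample_id: str
    treatments: dict = field(default_factory=dict)
    p1: Optional[float] = None
    p1_interval: Optional[tuple] = None
    p1_fixed: bool = False
    rg_nm: Optional[float] = None
    rg_interval_nm: Optional[tuple] = None
    p2: Optional[float] = None
    p2_interval: Optional[tuple] = None
    d_nm: Optional[float] = None
    d_interval_nm: Optional[tuple] = None
    d_fixed: bool = False

    def __post_init__(self):
        if self.d_nm is not None and self.d_nm <= 0:
            raise DomainError("EF spacing must be > 0 when present")


def _iv(result: FitResult, name: str):
    iv = result.intervals.get(name)
    if iv is None:
        return None
    return (iv.lo, iv.hi)


def _row_from_fits(sample_id, two_level, three_level, treatments):
    row = ReportRow(sample_id=sample_id, treatments=dict(treatments or {}))
    if two_level is not None:
        row.p1 = two_level.params.pl_exponent
        row.p1_fixed = "pl_exponent" in two_level.fixed
        row.p1_interval = None if row.p1_fixed else _iv(two_level, "pl_exponent")
        q0 = two_level.params.peak_center
        row.d_nm = ef_spacing_nm(q0)
        row.d_fixed = "peak_center" in two_level.fixed
        q0_iv = None if row.d_fixed else _iv(two_level, "peak_center")
        if q0_iv is not None:
            row.d_interval_nm = ef_spacing_interval_nm(q0_iv)
    if three_level is not None:
        row.rg_nm = three_level.params.level_Rg / 10.0
        rg_iv = _iv(three_level, "level_Rg")
        if rg_iv is not None:
            row.rg_interval_nm = (rg_iv[0] / 10.0, rg_iv[1] / 10.0)
        row.p2 = three_level.params.level_P2
        row.p2_interval = _iv(three_level, "level_P2")
        if two_level is None:
            # shavings protocol: P1 comes from the three-level fit, often fixed
            row.p1 = three_level.params.pl_exponent
            row.p1_fixed = "pl_exponent" in three_level.fixed
            row.p1_interval = None if row.p1_fixed else _iv(three_level, "pl_exponent")
    return row


def compile_report(fits: dict, metadata: Optional[pd.DataFrame] = None,
                   order: Optional[list] = None, round_to: int = 2) -> pd.DataFrame:
    """Assemble a study report table from per-sample fit results.

    Parameters
    ----------
    fits : dict
        ``{sample_id: {"two_level": FitResult | None,
                       "three_level": FitResult | None}}``.
    metadata : DataFrame, optional
        Indexed by sample_id with treatment-label columns.
    order : list of sample_id, optional
        Row order; defaults to dict order.
    round_to : int
        Decimal places for reported values (2 matches the study tables).
    """
    sample_ids = order if order is not None else list(fits)
    rows = []
    for sid in sample_ids:
        entry = fits.get(sid, {})
        treatments = {}
        if metadata is not None and sid in metadata.index:
            treatments = metadata.loc[sid].to_dict()
        row = _row_from_fits(sid, entry.get("two_level"), entry.get("three_level"),
                             treatments)
        rows.append(row)

    def fmt(value, fixed=False):
        if value is None:
            return None
        return round(value, round_to)

    records = []
    for row in rows:
        rec = {"sample_id": row.sample_id}
        for col in TREATMENT_COLUMNS:
            rec[col] = row.treatments.get(col)
        rec.update({
            "P1": fmt(row.p1),
            "P1_lo": fmt(row.p1_interval[0]) if row.p1_interval else None,
            "P1_hi": fmt(row.p1_interval[1]) if row.p1_interval else None,
            "P1_fixed": row.p1_fixed,
            "Rg_nm": fmt(row.rg_nm),
            "Rg_lo": fmt(row.rg_interval_nm[0]) if row.rg_interval_nm else None,
            "Rg_hi": fmt(row.rg_interval_nm[1]) if row.rg_interval_nm else None,
            "P2": fmt(row.p2),
            "P2_lo": fmt(row.p2_interval[0]) if row.p2_interval else None,
            "P2_hi": fmt(row.p2_interval[1]) if row.p2_interval else None,
            "d_nm": fmt(row.d_nm),
            "d_lo": fmt(row.d_interval_nm[0]) if row.d_interval_nm else None,
            "d_hi": fmt(row.d_interval_nm[1]) if row.d_interval_nm else None,
            "d_fixed": row.d_fixed,
        })
        records.append(rec)
    return pd.DataFrame.from_records(records)


def report_to_text(table: pd.DataFrame) -> str:
    """Human-readable rendering of a compiled report table."""
    if table.empty:
        return "(empty report)\n"

    def cell(row, value_col, lo, hi, fixed_col=None):
        v = row[value_col]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "-"
        s = f"{v:g}"
        if fixed_col is not None and row.get(fixed_col):
            return s + "**"
        if row.get(lo) is not None and row.get(hi) is not None \
                and not pd.isna(row.get(lo)) and not pd.isna(row.get(hi)):
            half = (row[hi] - row[lo]) / 2.0
            return f"{s} +/- {half:.2f}"
        return s

    lines = [f"{'Sample':<24}{'P1':>16}{'Rg (nm)':>16}{'P2':>16}{'EF spacing (nm)':>20}"]
    for _, row in table.iterrows():
        lines.append(
            f"{row['sample_id']:<24}"
            f"{cell(row, 'P1', 'P1_lo', 'P1_hi', 'P1_fixed'):>16}"
            f"{cell(row, 'Rg_nm', 'Rg_lo', 'Rg_hi'):>16}"
            f"{cell(row, 'P2', 'P2_lo', 'P2_hi'):>16}"
            f"{cell(row, 'd_nm', 'd_lo', 'd_hi', 'd_fixed'):>20}")
    return "\n".join(lines) + "\n"
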