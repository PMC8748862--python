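"""Luciferase reporter normalisation, growth-rate and viability arithmetic.

Dual-luciferase assays report two luminescence channels per well:
firefly (Fluc) and Renilla (Rluc).  In a bicistronic IRES reporter the
downstream Fluc is driven by the internal ribosome entry site and the
upstream Rluc by cap-dependent initiation, so the background-subtracted
Fluc/Rluc ratio measures IRES activity; in a co-transfected
monocistronic assay the same ratio measures cap-dependent translation of
the test 5'UTR.  The arithmetic is identical — the biological
interpretation lives in the experiment metadata, not in separate code
paths.

Fold-changes are expressed relative to the arithmetic mean of a control
condition (untreated, "NT"), which therefore has mean fold-change
exactly 1.  The same normalisation serves MTS viability readings
(percent of untreated).

Growth curves from impedance-based real-time monitoring (cell index vs
time) are summarised by the ordinary least-squares slope of the index
over a stated time window (e.g. a 72 h recovery window); a log-index
variant is available for exponential-phase data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fluoribo.errors import DataError


@dataclass(frozen=True)
class WellReading:
    """One plate well; blanks carry readings but no condition-level meaning."""

    well_id: str
    condition: str
    renilla: float
    firefly: float | None = None
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.renilla < 0 or (self.firefly is not None and self.firefly < 0):
            raise DataError("negative luminescence reading")


@dataclass(frozen=True)
class GrowthCurve:
    """Cell-index time series for one sample."""

    sample_id: str
    condition: str
    timepoints: tuple[float, ...]  # hours, strictly increasing
    index: tuple[float, ...]  # cell-index units

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise DataError("growth curve needs at least 2 timepoints")
        if len(self.timepoints) != len(self.index):
            raise DataError("timepoints and index lengths differ")
        t = np.asarray(self.timepoints)
        if not np.all(np.diff(t) > 0):
            raise DataError("timepoints must be strictly increasing")


def blank_means(readings: Sequence[WellReading]) -> tuple[float, float]:
    """Mean firefly and Renilla signal over blank wells (0, 0 when none)."""
    blanks = [r for r in readings if r.is_blank]
    if not blanks:
        return 0.0, 0.0
    fl = [r.firefly for r in blanks if r.firefly is not None]
    rl = [r.renilla for r in blanks]
    return (float(np.mean(fl)) if fl else 0.0, float(np.mean(rl)))


def luciferase_ratio(
    reading: WellReading, blank_mean_firefly: float = 0.0, blank_mean_renilla: float = 0.0
) -> float:
    """Background-subtracted Fluc/Rluc ratio for one well.

    Raises when the Renilla signal does not exceed its blank — a ratio
    against a below-background denominator is meaningless.
    """
    if reading.firefly is None:
        raise DataError(f"well {reading.well_id!r} has no firefly reading")
    renilla = reading.renilla - blank_mean_renilla
    if renilla <= 0:
        raise DataError(f"well {reading.well_id!r}: signal below background")
    return (reading.firefly - blank_mean_firefly) / renilla


def normalize_to_control(
    values: Sequence[float], conditions: Sequence[str], control: str
) -> np.ndarray:
    """Divide each value by the arithmetic mean of the control condition.

    Returns fold-changes aligned with the input; the control group's mean
    fold-change is exactly 1.
    """
    values = np.asarray(values, dtype=float)
    conditions = np.asarray(conditions)
    if len(values) != len(conditions):
        raise DataError("values and conditions lengths differ")
    mask = conditions == control
    if not mask.any():
        raise DataError(f"empty control group {control!r}")
    control_mean = values[mask].mean()
    if control_mean <= 0:
        raise DataError("control mean must be positive")
    return values / control_mean


def growth_rate(
    curve: GrowthCurve,
    window_start: float,
    window_end: float,
    log_index: bool = False,
) -> float:
    """OLS slope of cell index vs time within [window_start, window_end].

    With ``log_index=True`` the slope of log(index) is returned instead
    (per-hour exponential rate); index values must then be positive.
    """
    t = np.asarray(curve.timepoints, dtype=float)
    y = np.asarray(curve.index, dtype=float)
    mask = (t >= window_start) & (t <= window_end)
    if mask.sum() < 2:
        raise DataError(
            f"fewer than 2 timepoints in window [{window_start}, {window_end}]"
        )
    t, y = t[mask], y[mask]
    if log_index:
        if np.any(y <= 0):
            raise DataError("log_index requires positive index values")
        y = np.log(y)
    return float(stats.linregress(t, y).slope)


# ---------------------------------------------------------------------------
# CSV plumbing


def read_plate_csv(path) -> list[WellReading]:
    """Read a plate (well_id, condition, firefly, renilla, is_blank)."""
    df = pd.read_csv(path)
    required = {"well_id", "condition", "renilla"}
    if not required.issubset(df.columns):
        raise DataError(f"plate CSV missing columns: {sorted(required - set(df.columns))}")
    readings = []
    for _, row in df.iterrows():
        firefly = (
            float(row["firefly"])
            if "firefly" in df.columns and pd.notna(row.get("firefly"))
            else None
        )
        readings.append(
            WellReading(
                well_id=str(row["well_id"]),
                condition=str(row["condition"]),
                firefly=firefly,
                renilla=float(row["renilla"]),
                is_blank=bool(row["is_blank"]) if "is_blank" in df.columns else False,
            )
        )
    return readings


def read_growth_csv(path) -> list[GrowthCurve]:
    """Read growth curves (sample_id, condition, time_h, index), one curve per sample."""
    df = pd.read_csv(path)
    required = {"sample_id", "condition", "time_h", "index"}
    if not required.issubset(df.columns):
        raise DataError(f"growth CSV missing columns: {sorted(required - set(df.columns))}")
    curves = []
    for (sid, cond), grp in df.groupby(["sample_id", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                sample_id=str(sid),
                condition=str(cond),
                timepoints=tuple(float(v) for v in grp["time_h"]),
                index=tuple(float(v) for v in grp["index"]),
            )
        )
    return curves
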