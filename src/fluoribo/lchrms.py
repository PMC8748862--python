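"""LC-HRMS nucleoside quantification and the 5-FUrd-per-ribosome statistic.

Purified rRNA is enzymatically digested to nucleosides, spiked with a
stable-isotope-labelled internal standard, and quantified by liquid
chromatography / high-resolution mass spectrometry.  The pipeline starts
at integrated peak areas: the instrument response for an analyte is its
peak area divided by the internal-standard area, calibrated against
standards of known concentration by an ordinary least-squares line.

The number of 5-FUrd molecules per ribosome is then estimated from the
molar concentrations.  For a reference nucleoside X in {A, C, G} whose
per-ribosome copy number is N_X, the sample contains
``conc_X / N_X`` ribosome-equivalents, so

    estimate_X = (conc_5FUrd / conc_X) * N_X

is a dimensionless molecules-per-ribosome estimate.  The three
single-reference estimates are summarised by their mean and sample
standard deviation, exposing internal consistency of the measurement;
a pooled variant (ratio to the summed A+C+G concentration scaled by
N_A+N_C+N_G) is available via ``method="pooled"``.  Uridine is never a
reference: 5-FUrd substitutes for uridine, so conc_U depends on the
treatment itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fluoribo.composition import RibosomeComposition
from fluoribo.errors import DataError

#: Analyte name used for 5-fluorouridine throughout the CSV dialect.
FUIRD = "5FUrd"

#: Valid reference nucleosides for per-ribosome estimation.
VALID_REFERENCES = ("A", "C", "G")


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: known concentration vs instrument response."""

    analyte: str
    known_concentration: float  # molar units (e.g. nM)
    peak_area: float  # arbitrary instrument units
    internal_standard_area: float

    def __post_init__(self) -> None:
        if self.known_concentration < 0:
            raise DataError("negative standard concentration")
        if self.peak_area < 0:
            raise DataError("negative peak area")
        if self.internal_standard_area <= 0:
            raise DataError("non-positive internal-standard area")

    @property
    def response(self) -> float:
        """Internal-standard-normalised response ratio."""
        return self.peak_area / self.internal_standard_area


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of response ratio vs concentration for one analyte."""

    analyte: str
    slope: float  # response-ratio per concentration unit
    intercept: float
    r_squared: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DataError(f"non-positive calibration slope for {self.analyte}")
        if not self.range_low < self.range_high:
            raise DataError("degenerate calibration range")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise DataError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class Quantification:
    """A back-calculated concentration, flagged when extrapolated."""

    value: float
    out_of_range: bool


@dataclass(frozen=True)
class NucleosideMeasurement:
    """Molar nucleoside concentrations for one sample (same units throughout)."""

    sample_id: str
    conc_A: float
    conc_C: float
    conc_G: float
    conc_5FUrd: float
    conc_U: float | None = None

    def __post_init__(self) -> None:
        if self.conc_5FUrd < 0:
            raise DataError("negative 5-FUrd concentration")
        if self.conc_U is not None and self.conc_U < 0:
            raise DataError("negative U concentration")

    def conc(self, base: str) -> float:
        if base == FUIRD:
            return self.conc_5FUrd
        if base == "U":
            if self.conc_U is None:
                raise DataError(f"sample {self.sample_id!r}: conc_U not measured")
            return self.conc_U
        if base not in ("A", "C", "G"):
            raise DataError(f"unknown nucleoside {base!r}")
        return getattr(self, f"conc_{base}")


@dataclass(frozen=True)
class FluorinationEstimate:
    """5-FUrd molecules per ribosome, per reference nucleoside and summarised.

    ``detected`` is False when conc_5FUrd fell below the configured limit
    of detection; the numeric fields are still populated so callers can
    inspect the sub-LOD signal, but it should be reported as
    "not detected" rather than as a number.
    """

    sample_id: str
    per_reference: Mapping[str, float]
    mean: float
    sd: float
    n_references: int
    detected: bool = True

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise DataError("estimate requires at least one reference")


def fit_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationCurve:
    """Fit an OLS response-ratio vs concentration line for one analyte.

    Requires at least three standards at two or more distinct
    concentration levels.  Warns when r-squared falls below 0.99, the
    usual acceptability bound for an isotope-normalised nucleoside assay.
    """
    if len(standards) < 3:
        raise DataError("calibration requires at least 3 standards")
    analytes = {s.analyte for s in standards}
    if len(analytes) != 1:
        raise DataError(f"standards mix analytes: {sorted(analytes)}")
    conc = np.array([s.known_concentration for s in standards], dtype=float)
    resp = np.array([s.response for s in standards], dtype=float)
    if len(np.unique(conc)) < 2:
        raise DataError("degenerate design: all standards at one concentration")
    fit = stats.linregress(conc, resp)
    r2 = 1.0 if np.allclose(resp, fit.intercept + fit.slope * conc) else fit.rvalue**2
    if r2 < 0.99:
        warnings.warn(
            f"calibration for {standards[0].analyte}: r^2 = {r2:.4f} < 0.99",
            stacklevel=2,
        )
    return CalibrationCurve(
        analyte=standards[0].analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(min(r2, 1.0)),
        range_low=float(conc.min()),
        range_high=float(conc.max()),
    )


def quantify_concentration(
    peak_area: float, internal_standard_area: float, curve: CalibrationCurve
) -> Quantification:
    """Back-calculate a concentration from a peak area via the calibration line.

    ``concentration = (peak_area / IS_area - intercept) / slope``, clipped
    at zero; the result is flagged out-of-range when it falls outside the
    concentration span of the standards.
    """
    if internal_standard_area <= 0:
        raise DataError("non-positive internal-standard area")
    if peak_area < 0:
        raise DataError("negative peak area")
    raw = (peak_area / internal_standard_area - curve.intercept) / curve.slope
    value = max(raw, 0.0)
    out_of_range = not (curve.range_low <= raw <= curve.range_high)
    return Quantification(value=value, out_of_range=out_of_range)


def fuird_per_ribosome(
    m: NucleosideMeasurement,
    comp: RibosomeComposition,
    references: Sequence[str] = VALID_REFERENCES,
    method: str = "per_reference",
    lod: float | None = None,
) -> FluorinationEstimate:
    """Estimate 5-FUrd molecules per ribosome from one sample's concentrations.

    Parameters
    ----------
    m
        Measured concentrations (any single consistent molar unit).
    comp
        Per-ribosome base counts — the denominator of the statistic.
    references
        Non-empty subset of {A, C, G}.  U is rejected because 5-FUrd
        substitutes for uridine.
    method
        ``"per_reference"`` (default): one estimate per reference,
        summarised by mean and sample sd.  ``"pooled"``: single estimate
        conc_5FUrd / sum(conc_X) * sum(N_X) over the references.
    lod
        Optional limit of detection on conc_5FUrd (same units); below it
        the estimate is flagged not detected.
    """
    references = tuple(references)
    if not references:
        raise DataError("empty reference set")
    bad = [r for r in references if r not in VALID_REFERENCES]
    if bad:
        raise DataError(f"invalid reference nucleosides: {bad} (allowed: A, C, G)")
    for ref in references:
        if m.conc(ref) <= 0:
            raise DataError(
                f"sample {m.sample_id!r}: non-positive reference concentration [{ref}]"
            )
        if comp.count(ref) <= 0:
            raise DataError(f"composition has zero count for reference {ref}")

    detected = lod is None or m.conc_5FUrd >= lod
    if method == "per_reference":
        per_ref = {
            ref: (m.conc_5FUrd / m.conc(ref)) * comp.count(ref) for ref in references
        }
        values = np.array(list(per_ref.values()), dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    elif method == "pooled":
        total_conc = sum(m.conc(ref) for ref in references)
        total_n = sum(comp.count(ref) for ref in references)
        pooled = (m.conc_5FUrd / total_conc) * total_n
        per_ref = {"+".join(references): pooled}
        mean, sd = float(pooled), 0.0
    else:
        raise DataError(f"unknown method {method!r}")
    return FluorinationEstimate(
        sample_id=m.sample_id,
        per_reference=per_ref,
        mean=mean,
        sd=sd,
        n_references=len(references),
        detected=detected,
    )


# ---------------------------------------------------------------------------
# CSV plumbing


def read_standards_csv(path: str | Path) -> dict[str, list[CalibrationStandard]]:
    """Read standards (analyte, concentration, peak_area, is_area) grouped by analyte."""
    df = pd.read_csv(path)
    required = {"analyte", "concentration", "peak_area", "is_area"}
    if not required.issubset(df.columns):
        raise DataError(f"standards CSV missing columns: {sorted(required - set(df.columns))}")
    out: dict[str, list[CalibrationStandard]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["analyte"]), []).append(
            CalibrationStandard(
                analyte=str(row["analyte"]),
                known_concentration=float(row["concentration"]),
                peak_area=float(row["peak_area"]),
                internal_standard_area=float(row["is_area"]),
            )
        )
    return out


def measurements_from_areas(
    samples: pd.DataFrame, curves: Mapping[str, CalibrationCurve]
) -> tuple[list[NucleosideMeasurement], pd.DataFrame]:
    """Convert long-format sample areas into per-sample measurements.

    ``samples`` needs columns sample_id, analyte, peak_area, is_area with
    one row per (sample, analyte); analytes A, C, G and 5FUrd are
    required, U is optional.  Returns the measurements plus a flag table
    of out-of-range quantifications.
    """
    required = {"sample_id", "analyte", "peak_area", "is_area"}
    if not required.issubset(samples.columns):
        raise DataError(f"samples CSV missing columns: {sorted(required - set(samples.columns))}")
    flags = []
    out = []
    for sample_id, grp in samples.groupby("sample_id", sort=False):
        conc: dict[str, float] = {}
        for _, row in grp.iterrows():
            analyte = str(row["analyte"])
            if analyte not in curves:
                raise DataError(f"no calibration curve for analyte {analyte!r}")
            q = quantify_concentration(
                float(row["peak_area"]), float(row["is_area"]), curves[analyte]
            )
            conc[analyte] = q.value
            if q.out_of_range:
                flags.append({"sample_id": sample_id, "analyte": analyte, "flag": "out_of_range"})
        missing = {"A", "C", "G", FUIRD} - set(conc)
        if missing:
            raise DataError(f"sample {sample_id!r} missing analytes: {sorted(missing)}")
        out.append(
            NucleosideMeasurement(
                sample_id=str(sample_id),
                conc_A=conc["A"],
                conc_C=conc["C"],
                conc_G=conc["G"],
                conc_5FUrd=conc[FUIRD],
                conc_U=conc.get("U"),
            )
        )
    return out, pd.DataFrame(flags, columns=["sample_id", "analyte", "flag"])


def estimates_to_frame(estimates: Iterable[FluorinationEstimate]) -> pd.DataFrame:
    """Tabulate estimates (sample_id, est_A, est_C, est_G, mean, sd, flags)."""
    rows = []
    for e in estimates:
        row = {"sample_id": e.sample_id}
        for ref in VALID_REFERENCES:
            row[f"est_{ref}"] = e.per_reference.get(ref, math.nan)
        row["mean"] = e.mean
        row["sd"] = e.sd
        row["flags"] = "" if e.detected else "not_detected"
        rows.append(row)
    return pd.DataFrame(rows)
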