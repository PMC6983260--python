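"""Least-squares calibration, detection ranges and reader comparison.

Covers the three evaluation steps of a strip reader: fitting the dose
response (T/C characteristic value versus analyte concentration), fitting
the sensor's gray-versus-exposure line, and comparing the reader against a
reference instrument over their overlapping concentration range.  The
detection range of a protocol is simply the span of tested concentrations
whose readings pass the validity checks.

A reference CRP dilution-series table ships with the package
(``data/crp_dilution_series.csv``): T/C characteristic values from a commercial
lateral-flow reader and from the image reader with and without automatic
exposure adjustment, with invalid readings encoded as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .quantify import TCResult

__all__ = [
    "CalibrationFit",
    "RangeReport",
    "fit_linear",
    "detection_range",
    "compare_to_reference",
    "load_reference_table",
]

TABLE_COLUMNS = ("esequant_lfr", "without_adjustment", "with_adjustment")


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class RangeReport:
    """Valid-concentration span of one protocol; empty if nothing was valid."""

    lower: float | None
    upper: float | None
    valid_points: "list[float]"

    @property
    def empty(self) -> bool:
        return not self.valid_points


def fit_linear(xs, ys) -> CalibrationFit:
    """Ordinary least squares line with coefficient of determination."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("xs and ys must be equal-length 1-D sequences")
    if x.size < 2:
        raise DomainError("need at least 2 points to fit a line")
    if np.ptp(x) == 0:
        raise DomainError("xs are all equal; slope undefined")
    res = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    pred = res.slope * x + res.intercept
    ss_res = float(((y - pred) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=r2, n=int(x.size),
    )


def detection_range(concentrations, results) -> RangeReport:
    """Span of concentrations with valid readings.

    ``results`` may hold :class:`TCResult` objects or booleans (validity
    flags, with missing/NaN table entries counting as invalid).
    """
    concentrations = list(concentrations)
    results = list(results)
    if len(concentrations) != len(results):
        raise DomainError("concentrations and results must have equal length")
    valid = []
    for c, r in zip(concentrations, results):
        ok = r.valid if isinstance(r, TCResult) else bool(r) and not (
            isinstance(r, float) and np.isnan(r)
        )
        if ok:
            valid.append(float(c))
    if not valid:
        return RangeReport(lower=None, upper=None, valid_points=[])
    return RangeReport(lower=min(valid), upper=max(valid), valid_points=sorted(valid))


def compare_to_reference(
    device, reference, extend: bool = False
) -> CalibrationFit:
    """Fit device readings against a reference instrument.

    Both arguments are sequences of ``(concentration, ratio)`` pairs with
    NaN marking invalid readings.  With ``extend=False`` the fit uses the
    concentrations where both instruments read validly.  With
    ``extend=True`` the reference is first extended linearly: its valid
    readings are regressed on concentration and extrapolated to every
    concentration the device covers, mirroring the common practice of
    extending a narrow-range reference instrument to the full range of the
    device under test.
    """
    dev = {float(c): float(v) for c, v in device if not np.isnan(v)}
    ref = {float(c): float(v) for c, v in reference if not np.isnan(v)}
    if extend:
        if len(ref) < 2:
            raise DomainError("need >= 2 valid reference points to extend")
        line = fit_linear(list(ref), [ref[c] for c in ref])
        ref = {c: line.slope * c + line.intercept for c in dev}
    overlap = sorted(set(dev) & set(ref))
    if len(overlap) < 2:
        raise DomainError("need >= 2 overlapping valid concentrations")
    return fit_linear([ref[c] for c in overlap], [dev[c] for c in overlap])


def load_reference_table() -> pd.DataFrame:
    """Packaged CRP dilution-series comparison table.

    Columns: ``concentration_ug_per_ml`` plus one T/C characteristic-value
    column per instrument/protocol; invalid readings are NaN.
    """
    with resources.files("ficaread.data").joinpath("crp_dilution_series.csv").open() as fh:
        return pd.read_csv(fh)
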