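"""Reference wet-chemistry computations for the three quality components.

Tea polyphenols (TPs) are assayed colorimetrically with ferrous tartrate at
540 nm, free amino acids (FAA) with ninhydrin at 570 nm, and caffeine (CAF)
by UV absorbance at 274 nm.  FAA and CAF absorbances are converted to
masses/concentrations through linear standard curves; all three contents
are then expressed as dry-mass fraction (%) of the leaf sample.

Units
-----
* ``A1, A2, A3`` -- absorbances (AU) of the TPs / FAA / CAF assays.
* ``V1`` -- total test-solution volume (mL); ``V2`` -- aliquot volume (mL).
* ``m`` -- sample mass (g); ``omega`` -- dry-matter fraction on (0, 1].
* ``C1`` -- mg theanine in the measured aliquot (from the FAA curve).
* ``C2`` -- caffeine concentration, mg/mL (from the CAF curve).

The dilution constants embedded in the content formulas are implemented
verbatim; their provenance (calibration factor vs. dilution step) is not
decomposed further.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve", "fit_standard_curve", "invert_standard_curve",
    "tps_content", "faa_content", "caf_content", "assay_to_chemistry",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve ``A = slope * C + intercept``."""

    slope: float
    intercept: float
    r_squared: float
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be nonzero")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def fit_standard_curve(concentrations, absorbances, analyte: str = "") -> StandardCurve:
    """Ordinary least-squares line through calibration points.

    R^2 is the squared Pearson correlation between concentration and
    absorbance (identical to 1 - SSE/SST for a simple OLS line).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.ndim != 1 or c.shape != a.shape:
        raise ValueError("concentrations and absorbances must be equal-length 1-D")
    if c.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(c) == 0:
        raise ValueError("degenerate calibration: all concentrations equal")
    cc = c - c.mean()
    aa = a - a.mean()
    slope = float(cc @ aa / (cc @ cc))
    intercept = float(a.mean() - slope * c.mean())
    denom = float((cc @ cc) * (aa @ aa))
    r2 = float((cc @ aa) ** 2 / denom) if denom > 0 else 0.0
    return StandardCurve(slope=slope, intercept=intercept, r_squared=r2,
                         analyte=analyte)


def invert_standard_curve(curve: StandardCurve, absorbance):
    """Concentration ``(A - intercept) / slope`` read off the curve."""
    a = np.asarray(absorbance, dtype=float)
    out = (a - curve.intercept) / curve.slope
    return float(out) if np.isscalar(absorbance) or out.ndim == 0 else out


def _check_denominators(v1, v2, m, omega) -> None:
    for name, val in (("V1", v1), ("V2", v2), ("m", m), ("omega", omega)):
        if np.any(np.asarray(val, dtype=float) <= 0):
            raise ValueError(f"{name} must be positive")
    if np.any(np.asarray(v2, dtype=float) > np.asarray(v1, dtype=float)):
        raise ValueError("aliquot V2 cannot exceed total volume V1")


def _as_result(x):
    arr = np.asarray(x, dtype=float)
    return float(arr) if arr.ndim == 0 else arr


def tps_content(a1, v1, v2, m, omega):
    """Tea-polyphenol dry-mass fraction (%).

    ``TPs = A1 * 1.957 * 2 / 1000 * (V1/V2) / (m * omega) * 100``
    """
    _check_denominators(v1, v2, m, omega)
    if np.any(np.asarray(a1, dtype=float) < 0):
        raise ValueError("absorbance A1 must be nonnegative")
    a1, v1, v2, m, omega = map(np.asarray, (a1, v1, v2, m, omega))
    return _as_result(a1 * 1.957 * 2 / 1000.0 * (v1 / v2) / (m * omega) * 100.0)


def faa_content(c1, v1, v2, m, omega):
    """Free-amino-acid dry-mass fraction (%).

    ``FAA = C1/1000 * (V1/V2) / (m * omega) * 100`` with ``C1`` the mg of
    theanine found from the FAA standard curve.
    """
    _check_denominators(v1, v2, m, omega)
    if np.any(np.asarray(c1, dtype=float) < 0):
        raise ValueError("curve-derived mass C1 must be nonnegative")
    c1, v1, v2, m, omega = map(np.asarray, (c1, v1, v2, m, omega))
    return _as_result(c1 / 1000.0 * (v1 / v2) / (m * omega) * 100.0)


def caf_content(c2, v1, m, omega):
    """Caffeine dry-mass fraction (%).

    ``CAF = C2 * V1/1000 * (100/10) * (50/25) / (m * omega) * 100`` with
    ``C2`` in mg/mL from the CAF standard curve; the 10x and 2x factors are
    the clarification/dilution steps of the UV assay.
    """
    for name, val in (("V1", v1), ("m", m), ("omega", omega)):
        if np.any(np.asarray(val, dtype=float) <= 0):
            raise ValueError(f"{name} must be positive")
    if np.any(np.asarray(c2, dtype=float) < 0):
        raise ValueError("curve-derived concentration C2 must be nonnegative")
    c2, v1, m, omega = map(np.asarray, (c2, v1, m, omega))
    return _as_result(c2 * v1 / 1000.0 * (100.0 / 10.0) * (50.0 / 25.0)
                      / (m * omega) * 100.0)


def assay_to_chemistry(table: pd.DataFrame, faa_curve: StandardCurve,
                       caf_curve: StandardCurve) -> pd.DataFrame:
    """Convert raw assay measurements to per-sample contents.

    ``table`` needs columns ``sample_id, A1, A2, A3, V1, V2, m, omega``;
    any metadata columns (stage, time_h, replicate) are passed through.
    Returns a frame with added ``tps, faa, caf`` columns (%).
    """
    required = ["sample_id", "A1", "A2", "A3", "V1", "V2", "m", "omega"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    out = table.copy()
    c1 = invert_standard_curve(faa_curve, table["A2"].to_numpy(float))
    c2 = invert_standard_curve(caf_curve, table["A3"].to_numpy(float))
    c1 = np.clip(c1, 0.0, None)
    c2 = np.clip(c2, 0.0, None)
    v1 = table["V1"].to_numpy(float)
    v2 = table["V2"].to_numpy(float)
    m = table["m"].to_numpy(float)
    w = table["omega"].to_numpy(float)
    out["tps"] = tps_content(table["A1"].to_numpy(float), v1, v2, m, w)
    out["faa"] = faa_content(c1, v1, v2, m, w)
    out["caf"] = caf_content(c2, v1, m, w)
    return out
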