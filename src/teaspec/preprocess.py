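"""Spectral preprocessing: MSC, Savitzky-Golay smoothing, first derivative.

The chain removes the per-sample distortions that a leaf scene imposes on
its reflectance spectrum: multiplicative scatter correction (MSC) undoes
per-sample affine distortions against a reference spectrum, the forward
first difference removes additive baselines and sharpens overlapping
features, and Savitzky-Golay (S-G) local polynomial smoothing suppresses
sensor noise.  By default the chain operates on absorbance ``-log R``.

Two derivative flavours exist: the plain forward difference
``(y[i+1] - y[i]) / d_lambda`` (the default "d1" step) and the S-G
derivative (``savitzky_golay(..., deriv=1)``); they are distinct
operations and both are exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectralAxis, SpectrumMatrix

log = logging.getLogger(__name__)

KNOWN_STEPS = ("msc", "d1", "sg")


@dataclass(frozen=True)
class PreprocessConfig:
    """Ordered preprocessing chain and its parameters.

    ``steps`` is applied left to right.  The default ``msc -> d1 -> sg``
    follows the combined-pretreatment chain used for model building;
    window/polyorder are the S-G settings; ``domain`` selects whether the
    chain runs on reflectance or on absorbance ``-log R`` (default).
    """

    steps: tuple[str, ...] = ("msc", "d1", "sg")
    window: int = 11
    polyorder: int = 3
    msc_reference: np.ndarray | None = None
    domain: str = "absorbance"
    log_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("preprocessing chain must contain at least one step")
        unknown = [s for s in self.steps if s not in KNOWN_STEPS]
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {unknown}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("S-G window must be odd and greater than polyorder")
        if self.domain not in ("reflectance", "absorbance"):
            raise ValueError("domain must be 'reflectance' or 'absorbance'")


# ---------------------------------------------------------------------------
# array-level kernels

def msc_arrays(values: np.ndarray, reference: np.ndarray | None = None,
               sample_ids=None, tol: float = 1e-12):
    """Multiplicative scatter correction on a raw (samples x bands) array.

    Each spectrum ``x_i`` is regressed on the reference (OLS,
    ``x_i ~ a_i * ref + b_i``) and corrected to ``(x_i - b_i) / a_i``.

    Returns ``(corrected, slopes, intercepts)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("MSC needs a 2-D matrix with at least two bands")
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (x.shape[1],):
        raise ValueError("MSC reference length must match the band count")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom < tol:
        raise ValueError("MSC reference is constant; cannot regress on it")
    slopes = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(slopes) < tol):
        bad = int(np.argmin(np.abs(slopes)))
        name = sample_ids[bad] if sample_ids is not None else f"row {bad}"
        raise ValueError(
            f"MSC failed for sample {name}: spectrum is flat relative to the "
            f"reference (slope {slopes[bad]:.3e})")
    intercepts = x.mean(axis=1) - slopes * ref.mean()
    corrected = (x - intercepts[:, None]) / slopes[:, None]
    return corrected, slopes, intercepts


def savgol_arrays(values: np.ndarray, window: int = 11, polyorder: int = 3,
                  deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay filtering along the band axis.

    Edges are handled by evaluating the boundary polynomial fits
    (``mode="interp"``), so a degree <= polyorder polynomial is reproduced
    exactly everywhere.
    """
    x = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > x.shape[-1]:
        raise ValueError(f"window {window} exceeds band count {x.shape[-1]}")
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=deriv, axis=-1, mode="interp")


def derivative_arrays(values: np.ndarray, wavelengths: np.ndarray):
    """Forward-difference first derivative ``(y[i+1]-y[i]) / d_lambda``.

    Returns ``(derivative, midpoint_wavelengths)``; the output has one
    band fewer and lives on the interval midpoints, in units per nm.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size < 2:
        raise ValueError("first derivative needs at least two bands")
    dl = np.diff(wl)
    if np.any(dl <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    deriv = np.diff(x, axis=-1) / dl
    mid = 0.5 * (wl[:-1] + wl[1:])
    return deriv, mid


def to_absorbance_arrays(reflectance: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Absorbance ``-log R`` with reflectance floored at a small positive value."""
    r = np.clip(np.asarray(reflectance, dtype=float), floor, None)
    return -np.log(r)


# ---------------------------------------------------------------------------
# SpectrumMatrix-level operations

def to_absorbance(sm: SpectrumMatrix, floor: float = 1e-6) -> SpectrumMatrix:
    if sm.domain == "absorbance":
        return sm
    return sm.with_values(to_absorbance_arrays(sm.values, floor),
                          step="to_absorbance", domain="absorbance")


def msc(sm: SpectrumMatrix, reference: np.ndarray | None = None) -> SpectrumMatrix:
    corrected, slopes, intercepts = msc_arrays(
        sm.values, reference, sample_ids=sm.sample_ids)
    return sm.with_values(corrected, step="msc",
                          diagnostics={"msc_slopes": slopes,
                                       "msc_intercepts": intercepts})


def savitzky_golay(sm: SpectrumMatrix, window: int = 11,
                   polyorder: int = 3) -> SpectrumMatrix:
    return sm.with_values(savgol_arrays(sm.values, window, polyorder),
                          step=f"sg(w={window},p={polyorder})")


def first_derivative(sm: SpectrumMatrix) -> SpectrumMatrix:
    deriv, mid = derivative_arrays(sm.values, sm.axis.wavelengths)
    return sm.with_values(deriv, axis=SpectralAxis(mid), step="d1")


def apply_chain(sm: SpectrumMatrix, config: PreprocessConfig | None = None, *,
                msc_reference: np.ndarray | None = None) -> SpectrumMatrix:
    """Apply the configured chain in order, recording each step.

    ``msc_reference`` overrides the config reference (used to hold the
    reference at the training-set mean and avoid test-set leakage); when
    both are None the MSC reference is the column mean of the matrix at
    the point the step runs.
    """
    config = config if config is not None else PreprocessConfig()
    out = sm
    if config.domain == "absorbance" and out.domain == "reflectance":
        out = to_absorbance(out, config.log_floor)
    ref = msc_reference if msc_reference is not None else config.msc_reference
    for step in config.steps:
        if step == "msc":
            if out.n_bands < 2:
                raise ValueError("MSC requested with fewer than two bands left")
            step_ref = ref
            if step_ref is not None and len(step_ref) != out.n_bands:
                raise ValueError(
                    "MSC reference length does not match the current band "
                    "count (was it computed before a derivative step?)")
            out = msc(out, step_ref)
        elif step == "sg":
            out = savitzky_golay(out, config.window, config.polyorder)
        elif step == "d1":
            out = first_derivative(out)
    return out
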