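"""Hyperspectral cube I/O, reflectance correction and ROI extraction.

A raw scene is a ``height x width x n_bands`` stack of digital numbers
(DN).  Black/white correction converts DN to reflectance using a standard
whiteboard image ``W`` and a dark-current image ``B``::

    R = dn_max * (R0 - B) / (W - B)

with ``dn_max`` the sensor's DN ceiling (default 65,552).  The sample's
spectrum is then the per-band mean over a region-of-interest (ROI) mask.

Cubes round-trip through a deliberately small ENVI dialect: a text
``.hdr`` plus a raw binary file, band-sequential (BSQ), little-endian,
unsigned 16- or 32-bit integers.  No other interleave or dtype is read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (METADATA_COLUMNS, STAGES, SpectralAxis,
                         SpectrumMatrix)
import pandas as pd

log = logging.getLogger(__name__)

#: DN ceiling as used in the correction formula.  Deliberately 65,552 (not
#: 2**16 - 1); configurable on every cube.
DEFAULT_DN_MAX = 65552

_DTYPE_CODES = {12: np.dtype("<u2"), 13: np.dtype("<u4")}
_CODE_FOR_DTYPE = {v: k for k, v in _DTYPE_CODES.items()}


@dataclass
class HyperspectralCube:
    """DN image stack with its wavelength axis.

    ``data`` is ``(height, width, n_bands)``.  DN values are integer
    sensor counts, but float arrays are accepted for intermediate
    arithmetic (I/O always writes integers).
    """

    data: np.ndarray
    axis: SpectralAxis
    dn_max: int = DEFAULT_DN_MAX

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (height, width, bands)")
        if self.data.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis has "
                f"{self.axis.n_bands}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > self.dn_max):
            raise ValueError(f"DN values must lie in [0, {self.dn_max}]")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ReflectanceImage:
    """Corrected reflectance on the DN scale, with a per-pixel validity mask.

    A pixel is invalid when ``W == B`` at any band (the correction is
    undefined there).  Out-of-range reflectance (specular highlights) is
    retained, not clipped -- clipping would bias ROI means -- but counted
    in ``n_out_of_range``.
    """

    data: np.ndarray
    valid: np.ndarray
    axis: SpectralAxis
    dn_max: int = DEFAULT_DN_MAX
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.valid.shape != self.data.shape[:2]:
            raise ValueError("reflectance data must be 3-D with a (h, w) mask")


def correct_reflectance(raw: HyperspectralCube, white: HyperspectralCube,
                        black: HyperspectralCube) -> ReflectanceImage:
    """Black/white reflectance correction ``R = dn_max * (R0-B)/(W-B)``."""
    for name, cube in (("white", white), ("black", black)):
        if cube.data.shape != raw.data.shape:
            raise ValueError(
                f"shape mismatch: {name} reference {cube.data.shape} vs raw "
                f"{raw.data.shape}")
        if cube.axis != raw.axis:
            raise ValueError(f"axis mismatch between raw cube and {name} reference")
    r0 = raw.data.astype(float)
    w = white.data.astype(float)
    b = black.data.astype(float)
    denom = w - b
    valid = np.all(denom != 0, axis=2)
    if not valid.any():
        raise ValueError("all pixels invalid: white and black references coincide")
    out = np.full_like(r0, np.nan)
    out[valid] = raw.dn_max * (r0[valid] - b[valid]) / denom[valid]
    n_oor = int(np.sum((out[valid] < 0) | (out[valid] > raw.dn_max)))
    if n_oor:
        log.info("reflectance correction: %d band values outside [0, %d] retained",
                 n_oor, raw.dn_max)
    return ReflectanceImage(data=out, valid=valid, axis=raw.axis,
                            dn_max=raw.dn_max, n_out_of_range=n_oor)


def extract_roi_mean(image: ReflectanceImage, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean spectrum over the masked valid pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.data.shape[:2]:
        raise ValueError("ROI mask shape does not match the image")
    effective = mask & image.valid
    if not effective.any():
        raise ValueError("ROI mask selects no valid pixels")
    return image.data[effective].mean(axis=0)


def threshold_roi(image: ReflectanceImage, band: int | None = None,
                  quantile: float = 0.5) -> np.ndarray:
    """Whole-sample ROI helper: pixels brighter than a quantile threshold.

    Stands in for interactive ROI drawing; ``band`` defaults to the middle
    band.
    """
    band = image.data.shape[2] // 2 if band is None else band
    plane = image.data[:, :, band]
    thr = np.nanquantile(plane[image.valid], quantile)
    return (plane >= thr) & image.valid


# ---------------------------------------------------------------------------
# minimal ENVI dialect

def write_cube(cube: HyperspectralCube, path) -> None:
    """Write a cube as ``<base>.hdr`` + ``<base>.img`` (BSQ, little-endian)."""
    base = Path(path)
    if base.suffix in (".hdr", ".img"):
        base = base.with_suffix("")
    dtype = np.dtype("<u2") if cube.dn_max <= 0xFFFF else np.dtype("<u4")
    h, w, nb = cube.data.shape
    wl = ", ".join(f"{v:.6f}" for v in cube.axis.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {nb}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR_DTYPE[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"dn max = {cube.dn_max}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    base.with_suffix(".hdr").write_text(header)
    bsq = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)).astype(dtype))
    bsq.tofile(base.with_suffix(".img"))


def _parse_header(text: str) -> dict:
    # fold the brace-delimited wavelength list onto one logical line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (or a compatible header)."""
    base = Path(path)
    if base.suffix in (".hdr", ".img"):
        base = base.with_suffix("")
    hdr_path = base.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing header file: {hdr_path}")
    fields = _parse_header(hdr_path.read_text())
    for key in ("samples", "lines", "bands", "data type", "interleave",
                "byte order", "wavelength"):
        if key not in fields:
            raise ValueError(f"missing header field: {key}")
    if fields["interleave"].lower() != "bsq":
        raise ValueError(f"unsupported interleave: {fields['interleave']} "
                         "(only bsq is supported)")
    if fields["byte order"] != "0":
        raise ValueError("unsupported byte order (only little-endian, 0)")
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise ValueError(f"unsupported data type code: {code} "
                         f"(supported: {sorted(_DTYPE_CODES)})")
    w, h, nb = (int(fields[k]) for k in ("samples", "lines", "bands"))
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = [float(tok) for tok in wl_text.replace(",", " ").split()]
    if len(wavelengths) != nb:
        raise ValueError(
            f"header band count {nb} does not match wavelength list length "
            f"{len(wavelengths)}")
    dn_max = int(fields.get("dn max", DEFAULT_DN_MAX))
    dtype = _DTYPE_CODES[code]
    data = np.fromfile(base.with_suffix(".img"), dtype=dtype)
    if data.size != h * w * nb:
        raise ValueError(
            f"data file size mismatch: expected {h * w * nb} values, found "
            f"{data.size}")
    cube_data = np.transpose(data.reshape(nb, h, w), (1, 2, 0))
    return HyperspectralCube(data=cube_data, axis=SpectralAxis(wavelengths),
                             dn_max=dn_max)


# ---------------------------------------------------------------------------

def build_spectrum_matrix(samples, axis: SpectralAxis,
                          domain: str = "reflectance") -> SpectrumMatrix:
    """Stack per-sample spectra into a canonical SpectrumMatrix.

    ``samples`` is an iterable of ``(spectrum, metadata)`` pairs where
    metadata is a mapping with keys ``sample_id, stage, time_h,
    replicate``.  Rows are sorted by (stage in processing order, time,
    replicate) so the result is independent of input order.
    """
    rows, meta = [], []
    for spectrum, md in samples:
        spec = np.asarray(spectrum, dtype=float)
        if spec.shape != (axis.n_bands,):
            raise ValueError(
                f"sample {md.get('sample_id', '?')}: spectrum length "
                f"{spec.shape} does not match axis ({axis.n_bands} bands)")
        rows.append(spec)
        meta.append({k: md[k] for k in METADATA_COLUMNS})
    if not rows:
        raise ValueError("no samples given")
    frame = pd.DataFrame(meta)
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
    stage_order = {s: i for i, s in enumerate(STAGES)}
    order = frame.assign(_s=frame["stage"].map(stage_order)) \
                 .sort_values(["_s", "time_h", "replicate"], kind="stable") \
                 .index.to_numpy()
    values = np.vstack([rows[i] for i in order])
    return SpectrumMatrix(values=values, axis=axis,
                          metadata=frame.iloc[order].reset_index(drop=True),
                          domain=domain)
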