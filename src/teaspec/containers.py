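"""Core data containers shared across the pipeline.

The central currency is the :class:`SpectrumMatrix`: an ``n_samples x
n_bands`` table of reflectance (or absorbance) values on a common
:class:`SpectralAxis`, with per-sample metadata (stage, sampling time,
replicate).  Reference chemistry travels as a :class:`ChemistryTable`
holding the three quality components as dry-mass-fraction percent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Default number of spectral bands of the imaging system.
DEFAULT_N_BANDS = 360
#: Default wavelength span of the visible/NIR camera, nm.
DEFAULT_RANGE_NM = (391.0, 1010.0)
#: The predicted quality components, as dry-mass-fraction percent.
ANALYTES = ("tps", "faa", "caf")
#: Processing stages, in processing order.
STAGES = ("withering", "fermentation")
#: Required per-sample metadata columns, in canonical order.
METADATA_COLUMNS = ("sample_id", "stage", "time_h", "replicate")

_DOMAINS = ("reflectance", "absorbance")


class SpectralAxis:
    """Strictly increasing wavelength axis in nanometres."""

    __slots__ = ("wavelengths",)

    def __init__(self, wavelengths) -> None:
        wl = np.array(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectral axis needs at least two wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        wl.setflags(write=False)
        self.wavelengths = wl

    @classmethod
    def default(cls, n_bands: int = DEFAULT_N_BANDS,
                low: float = DEFAULT_RANGE_NM[0],
                high: float = DEFAULT_RANGE_NM[1]) -> "SpectralAxis":
        """Evenly spaced axis over the camera's 391-1010 nm range."""
        return cls(np.linspace(low, high, n_bands))

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def midpoints(self) -> "SpectralAxis":
        """Axis of interval midpoints (used after a forward difference)."""
        wl = self.wavelengths
        return SpectralAxis(0.5 * (wl[:-1] + wl[1:]))

    def nearest_index(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def __len__(self) -> int:
        return self.n_bands

    def __eq__(self, other) -> bool:
        return (isinstance(other, SpectralAxis)
                and self.n_bands == other.n_bands
                and np.allclose(self.wavelengths, other.wavelengths))

    def __repr__(self) -> str:
        wl = self.wavelengths
        return f"SpectralAxis({wl[0]:.2f}..{wl[-1]:.2f} nm, {wl.size} bands)"


def _check_metadata(metadata: pd.DataFrame, n_rows: int) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if len(metadata) != n_rows:
        raise ValueError(
            f"metadata has {len(metadata)} rows for {n_rows} samples")
    if metadata["sample_id"].duplicated().any():
        dup = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
    return metadata.reset_index(drop=True)


@dataclass
class SpectrumMatrix:
    """Per-sample spectra on a shared wavelength axis.

    Parameters
    ----------
    values
        ``(n_samples, n_bands)`` array, reflectance on [0, 1] (or a DN
        scale) or absorbance, per ``domain``.
    axis
        Shared wavelength axis.
    metadata
        One row per sample with columns ``sample_id, stage, time_h,
        replicate``.
    domain
        ``"reflectance"`` or ``"absorbance"``.
    applied_steps
        Ordered record of the preprocessing already applied.
    """

    values: np.ndarray
    axis: SpectralAxis
    metadata: pd.DataFrame
    domain: str = "reflectance"
    applied_steps: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x bands) array")
        if self.values.shape[1] != self.axis.n_bands:
            raise ValueError(
                f"values have {self.values.shape[1]} bands but axis has "
                f"{self.axis.n_bands}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum matrix contains non-finite values")
        if self.domain not in _DOMAINS:
            raise ValueError(f"domain must be one of {_DOMAINS}")
        self.metadata = _check_metadata(self.metadata, self.values.shape[0])
        self.applied_steps = tuple(self.applied_steps)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.metadata["sample_id"].to_numpy()

    def with_values(self, values: np.ndarray, *, axis: SpectralAxis | None = None,
                    step: str | None = None, domain: str | None = None,
                    diagnostics: dict | None = None) -> "SpectrumMatrix":
        """Copy with new values and an optional applied-step record."""
        steps = self.applied_steps + ((step,) if step else ())
        diag = dict(self.diagnostics)
        if diagnostics:
            diag.update(diagnostics)
        return SpectrumMatrix(values=np.asarray(values, dtype=float),
                              axis=axis if axis is not None else self.axis,
                              metadata=self.metadata.copy(),
                              domain=domain if domain is not None else self.domain,
                              applied_steps=steps,
                              diagnostics=diag)

    def select_rows(self, index: np.ndarray) -> "SpectrumMatrix":
        return SpectrumMatrix(values=self.values[index],
                              axis=self.axis,
                              metadata=self.metadata.iloc[index].reset_index(drop=True),
                              domain=self.domain,
                              applied_steps=self.applied_steps)

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as CSV: comment header lines, then metadata + one column
        per wavelength (nm, 2 decimals)."""
        cols = [f"{w:.2f}" for w in self.axis.wavelengths]
        frame = pd.concat(
            [self.metadata[list(METADATA_COLUMNS)],
             pd.DataFrame(self.values, columns=cols)], axis=1)
        with open(path, "w") as fh:
            fh.write(f"# domain: {self.domain}\n")
            fh.write(f"# applied_steps: {','.join(self.applied_steps)}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumMatrix":
        domain, steps = "reflectance", ()
        text = Path(path).read_text()
        body_lines = []
        for line in text.splitlines():
            if line.startswith("# domain:"):
                domain = line.split(":", 1)[1].strip()
            elif line.startswith("# applied_steps:"):
                raw = line.split(":", 1)[1].strip()
                steps = tuple(s for s in raw.split(",") if s)
            elif line.startswith("#"):
                continue
            else:
                body_lines.append(line)
        frame = pd.read_csv(io.StringIO("\n".join(body_lines)))
        meta = frame[list(METADATA_COLUMNS)].copy()
        wl_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
        axis = SpectralAxis([float(c) for c in wl_cols])
        return cls(values=frame[wl_cols].to_numpy(float), axis=axis,
                   metadata=meta, domain=domain, applied_steps=steps)


@dataclass
class ChemistryTable:
    """Per-sample reference chemistry (dry-mass-fraction %).

    ``data`` holds the metadata columns plus one column per analyte with
    the *measured* (assay) value.  Optional ``<analyte>_true`` columns
    carry the noise-free-of-assay-error values that drive synthetic
    spectra; they fall back to the measured columns when absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _check_metadata(self.data, len(self.data))

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(a for a in ANALYTES if a in self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy()

    def values(self, analytes=None) -> np.ndarray:
        analytes = tuple(analytes) if analytes is not None else self.analytes
        return self.data[list(analytes)].to_numpy(float)

    def true_values(self, analytes=None) -> np.ndarray:
        """Values driving the spectra; measured values if no *_true columns."""
        analytes = tuple(analytes) if analytes is not None else self.analytes
        cols = [a + "_true" if a + "_true" in self.data.columns else a
                for a in analytes]
        return self.data[cols].to_numpy(float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChemistryTable":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, tables) -> "ChemistryTable":
        return cls(pd.concat([t.data for t in tables], ignore_index=True))
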