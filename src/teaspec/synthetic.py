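"""Synthetic hyperspectral tea dataset generator.

The study's real dataset (116 leaf samples imaged hourly through withering
and half-hourly through fermentation) is not publicly deposited, so this
module provides a forward model with the statistical structure the
analysis pipeline assumes:

* concentration *trajectories* follow black-tea processing kinetics --
  polyphenols (TPs) fall through withering and drop sharply early in
  fermentation, free amino acids (FAA) rise to a 16 h plateau during
  withering, caffeine (CAF) stays level;
* *spectra* are Beer-Lambert mixtures of synthetic Gaussian
  pure-component absorptivity profiles (real tea signatures are not
  available; the acceptance surface is parameter recovery, not spectral
  realism), with per-sample multiplicative/additive scatter, linear
  baseline drift, an exponential reflectance link ``R = exp(-A)`` and
  i.i.d. sensor noise;
* *cubes* invert the black/white correction so the full raw-DN path can
  be exercised end to end.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (ANALYTES, STAGES, ChemistryTable, SpectralAxis,
                         SpectrumMatrix)
from .cube_io import DEFAULT_DN_MAX, HyperspectralCube

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sampling schedules

@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling plan of one processing stage."""

    stage: str
    time_points_h: tuple[float, ...]
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.replicates < 1 or not self.time_points_h:
            raise ValueError("schedule needs >= 1 time point and >= 1 replicate")

    @classmethod
    def withering(cls, replicates: int = 4) -> "SamplingSchedule":
        """19 hourly samplings, 1..19 h."""
        return cls("withering", tuple(float(t) for t in range(1, 20)), replicates)

    @classmethod
    def fermentation(cls, replicates: int = 4) -> "SamplingSchedule":
        """10 half-hourly samplings, 0.5..5.0 h."""
        return cls("fermentation", tuple(0.5 * t for t in range(1, 11)), replicates)

    @property
    def n_samples(self) -> int:
        return len(self.time_points_h) * self.replicates


def default_schedules(replicates: int = 4) -> tuple[SamplingSchedule, ...]:
    """The study layout: 76 withering + 40 fermentation = 116 samples."""
    return (SamplingSchedule.withering(replicates),
            SamplingSchedule.fermentation(replicates))


# ---------------------------------------------------------------------------
# pure-component spectra

@dataclass(frozen=True)
class GaussianPeak:
    """One Gaussian absorptivity peak: AU per unit concentration (%)."""

    center_nm: float
    width_nm: float
    height: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("peak width must be positive")
        if self.height < 0:
            raise ValueError("peak height must be nonnegative")


@dataclass
class PureComponentLibrary:
    """Nonnegative absorptivity profiles on a shared axis.

    ``analytes`` maps the predicted components to their profiles;
    ``interferents`` holds additional absorbing components (leaf matrix,
    pigments) whose concentrations are nuisance variables drawn uniformly
    from ``interferent_ranges``.
    """

    axis: SpectralAxis
    analytes: dict[str, np.ndarray]
    interferents: dict[str, np.ndarray] = field(default_factory=dict)
    interferent_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, profile in {**self.analytes, **self.interferents}.items():
            if profile.shape != (self.axis.n_bands,):
                raise ValueError(f"profile '{name}' does not match the axis")
            if np.any(profile < 0):
                raise ValueError(f"profile '{name}' has negative absorptivity")
        for name in self.interferents:
            self.interferent_ranges.setdefault(name, (0.5, 1.5))

    def profile_matrix(self, names: Sequence[str]) -> np.ndarray:
        """(len(names) x n_bands) matrix of analyte profiles."""
        return np.vstack([self.analytes[n] for n in names])

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.profile_matrix(list(self.analytes)).T))


def _gaussian(axis: SpectralAxis, peak: GaussianPeak) -> np.ndarray:
    wl = axis.wavelengths
    return peak.height * np.exp(-0.5 * ((wl - peak.center_nm) / peak.width_nm) ** 2)


def make_pure_spectra(axis: SpectralAxis,
                      peak_params: Mapping[str, Sequence],
                      analytes: Sequence[str] = ANALYTES,
                      interferent_ranges: Mapping[str, tuple[float, float]] | None = None,
                      ) -> PureComponentLibrary:
    """Build a component library from Gaussian peak specifications.

    ``peak_params`` maps component name to a list of peaks (``GaussianPeak``
    or ``(center, width, height)`` tuples).  Components named in
    ``analytes`` must each have at least one peak -- an analyte without a
    spectral signature would be invisible to the whole pipeline.
    """
    lo, hi = axis.wavelengths[0], axis.wavelengths[-1]
    profiles: dict[str, np.ndarray] = {}
    for name, peaks in peak_params.items():
        peaks = [p if isinstance(p, GaussianPeak) else GaussianPeak(*p)
                 for p in peaks]
        if name in analytes and not peaks:
            raise ValueError(
                f"analyte '{name}' has no peaks and would be spectrally invisible")
        for p in peaks:
            if not lo <= p.center_nm <= hi:
                raise ValueError(
                    f"peak center {p.center_nm} nm outside axis [{lo}, {hi}]")
        profile = np.zeros(axis.n_bands)
        for p in peaks:
            profile += _gaussian(axis, p)
        profiles[name] = profile
    missing = [a for a in analytes if a not in profiles]
    if missing:
        raise ValueError(f"analytes without peak specifications: {missing}")
    return PureComponentLibrary(
        axis=axis,
        analytes={a: profiles[a] for a in analytes},
        interferents={n: p for n, p in profiles.items() if n not in analytes},
        interferent_ranges=dict(interferent_ranges or {}))


def default_library(axis: SpectralAxis | None = None) -> PureComponentLibrary:
    """Default synthetic signatures: three analytes plus one leaf-matrix
    interferent with broad overlapping absorption."""
    axis = axis if axis is not None else SpectralAxis.default()
    peaks = {
        "tps": [(540, 45, 0.050), (680, 60, 0.035), (930, 80, 0.020)],
        "faa": [(470, 40, 0.190), (760, 55, 0.160), (990, 70, 0.110)],
        "caf": [(430, 35, 0.220), (610, 50, 0.260), (870, 65, 0.170)],
        "leaf_matrix": [(700, 150, 1.40), (450, 60, 1.00), (900, 200, 1.00)],
    }
    return make_pure_spectra(axis, peaks,
                             interferent_ranges={"leaf_matrix": (0.97, 1.03)})


# ---------------------------------------------------------------------------
# concentration trajectories

@dataclass(frozen=True)
class TrajectorySegment:
    """Linear ramp from ``start`` to ``end`` between onset and offset, flat
    outside; constant when start == end."""

    start: float
    end: float
    onset_h: float = 0.0
    offset_h: float = 1.0

    def mean(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.offset_h <= self.onset_h:
            return np.full_like(t, self.end, dtype=float)
        frac = np.clip((t - self.onset_h) / (self.offset_h - self.onset_h), 0, 1)
        return self.start + (self.end - self.start) * frac


@dataclass
class TrajectoryParams:
    """Noise-free trajectory means plus the two noise layers.

    ``replicate_sd`` is real leaf-to-leaf variation (it drives the
    spectra); ``measurement_sd`` is assay error on the reported chemistry
    only.  ``envelopes`` bound the generated concentrations; violations
    are clipped (and logged) by default, or raise in strict mode.
    """

    segments: dict[tuple[str, str], TrajectorySegment]
    replicate_sd: dict[str, float]
    measurement_sd: dict[str, float]
    envelopes: dict[str, tuple[float, float]]

    def mean(self, stage: str, analyte: str, times) -> np.ndarray:
        return self.segments[(stage, analyte)].mean(times)


def default_trajectory_params() -> TrajectoryParams:
    """The study conditions: TPs fall 1-16 h of withering and 0-3 h of
    fermentation; FAA rises to a 16 h withering plateau; CAF stays level.
    Envelopes are the observed min/max of each component."""
    seg = {
        ("withering", "tps"): TrajectorySegment(12.90, 10.70, 1.0, 16.0),
        ("withering", "faa"): TrajectorySegment(4.30, 5.95, 1.0, 16.0),
        ("withering", "caf"): TrajectorySegment(4.85, 4.85),
        ("fermentation", "tps"): TrajectorySegment(10.70, 6.40, 0.0, 3.0),
        ("fermentation", "faa"): TrajectorySegment(5.00, 5.00),
        ("fermentation", "caf"): TrajectorySegment(4.85, 4.85),
    }
    return TrajectoryParams(
        segments=seg,
        replicate_sd={"tps": 0.35, "faa": 0.15, "caf": 0.25},
        measurement_sd={"tps": 0.25, "faa": 0.05, "caf": 0.10},
        envelopes={"tps": (6.00, 13.28), "faa": (4.11, 6.13),
                   "caf": (4.21, 5.52)})


def simulate_trajectories(schedule: SamplingSchedule,
                          params: TrajectoryParams | None = None,
                          seed: int = 0, strict: bool = False) -> ChemistryTable:
    """Draw per-sample chemistry for one stage.

    Each sample gets a *true* content (trajectory mean + replicate
    variation) and a *measured* content (true + assay error); both are
    clipped to the analyte envelope.  The measured values sit in the
    analyte columns, the true values in ``<analyte>_true``.
    """
    params = params if params is not None else default_trajectory_params()
    rng = np.random.default_rng(seed)
    rows = []
    prefix = schedule.stage[:4]
    for ti, t in enumerate(schedule.time_points_h, start=1):
        for r in range(1, schedule.replicates + 1):
            rows.append({"sample_id": f"{prefix}_t{ti:02d}_r{r}",
                         "stage": schedule.stage, "time_h": t, "replicate": r})
    frame = pd.DataFrame(rows)
    times = frame["time_h"].to_numpy(float)
    n_clipped = 0
    for analyte in ANALYTES:
        mean = params.mean(schedule.stage, analyte, times)
        true = mean + rng.normal(0.0, params.replicate_sd[analyte], times.size)
        measured = true + rng.normal(0.0, params.measurement_sd[analyte],
                                     times.size)
        lo, hi = params.envelopes[analyte]
        for arr in (true, measured):
            outside = (arr < lo) | (arr > hi)
            if outside.any():
                if strict:
                    raise ValueError(
                        f"{analyte}: {int(outside.sum())} values outside the "
                        f"envelope [{lo}, {hi}] (strict mode)")
                n_clipped += int(outside.sum())
                np.clip(arr, lo, hi, out=arr)
        frame[analyte] = measured
        frame[analyte + "_true"] = true
    if n_clipped:
        log.info("simulate_trajectories(%s): clipped %d values to envelopes",
                 schedule.stage, n_clipped)
    return ChemistryTable(frame)


# ---------------------------------------------------------------------------
# spectra and cubes

@dataclass(frozen=True)
class NoiseModel:
    """Per-sample distortions applied in absorbance, plus sensor noise.

    With every range degenerate and ``iid_sd`` zero, synthesis is exact
    Beer-Lambert mixing.
    """

    multiplicative_range: tuple[float, float] = (0.97, 1.03)
    additive_range_au: tuple[float, float] = (-0.05, 0.05)
    drift_slope_range_au_per_nm: tuple[float, float] = (-1e-4, 1e-4)
    iid_sd: float = 5e-5
    edge_noise_factor: float = 2.0
    reflectance_floor: float = 1e-4

    def band_sd(self, wavelengths: np.ndarray) -> np.ndarray:
        """Per-band noise SD: ``iid_sd`` mid-spectrum, rising quadratically
        to ``iid_sd * edge_noise_factor`` at the spectral edges (detector
        quantum efficiency rolls off at both ends of a VNIR range)."""
        wl = np.asarray(wavelengths, dtype=float)
        x = 2.0 * (wl - wl.mean()) / (wl[-1] - wl[0])
        return self.iid_sd * (1.0 + (self.edge_noise_factor - 1.0) * x ** 2)

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(multiplicative_range=(1.0, 1.0), additive_range_au=(0.0, 0.0),
                   drift_slope_range_au_per_nm=(0.0, 0.0), iid_sd=0.0)


def synthesize_spectra(chem: ChemistryTable, library: PureComponentLibrary,
                       noise: NoiseModel | None = None,
                       seed: int = 0) -> SpectrumMatrix:
    """Forward model chemistry -> reflectance spectra.

    Absorbance ``A_i = sum_k c_ik s_k + interferents``, then per-sample
    scatter/drift, ``R = exp(-A)`` clipped to [0, 1], then i.i.d. noise
    floored at a small positive reflectance.
    """
    noise = noise if noise is not None else NoiseModel()
    names = tuple(library.analytes)
    missing = [a for a in names if a not in chem.data.columns]
    if missing:
        raise ValueError(f"chemistry table lacks analyte columns: {missing}")
    rng = np.random.default_rng(seed)
    conc = chem.true_values(names)                       # (n, k)
    profiles = library.profile_matrix(names)             # (k, p)
    absorbance = conc @ profiles
    n = conc.shape[0]
    for name, profile in library.interferents.items():
        lo, hi = library.interferent_ranges[name]
        absorbance += rng.uniform(lo, hi, n)[:, None] * profile
    wl = library.axis.wavelengths
    slopes = rng.uniform(*noise.multiplicative_range, n)
    offsets = rng.uniform(*noise.additive_range_au, n)
    drifts = rng.uniform(*noise.drift_slope_range_au_per_nm, n)
    absorbance = (slopes[:, None] * absorbance + offsets[:, None]
                  + drifts[:, None] * (wl - wl.mean())[None, :])
    reflectance = np.clip(np.exp(-absorbance), 0.0, 1.0)
    if noise.iid_sd > 0:
        reflectance = reflectance + (rng.normal(0.0, 1.0, reflectance.shape)
                                     * noise.band_sd(wl)[None, :])
    n_floored = int(np.sum(reflectance < noise.reflectance_floor))
    if n_floored:
        log.info("synthesize_spectra: floored %d reflectance values", n_floored)
    reflectance = np.clip(reflectance, noise.reflectance_floor, None)
    meta = chem.data[["sample_id", "stage", "time_h", "replicate"]].copy()
    return SpectrumMatrix(values=reflectance, axis=library.axis, metadata=meta,
                          domain="reflectance")


def synthesize_cube(spectrum: np.ndarray, axis: SpectralAxis,
                    shape: tuple[int, int] = (8, 8),
                    dn_max: int = DEFAULT_DN_MAX, seed: int = 0,
                    white_level: float | None = None, black_level: float = 0.0,
                    jitter_sd: float = 0.0):
    """Invert the black/white correction for one sample spectrum.

    ``spectrum`` is reflectance on the DN scale ``[0, dn_max]``.  Returns
    ``(raw, white, black)`` cubes such that correcting the raw cube with
    the emitted references recovers the spectrum up to DN quantization.
    With the default references (W = dn_max, B = 0) the per-pixel rounding
    error is at most 0.5 DN; narrower W - B spans scale it up by
    ``dn_max / (W - B)``.  ``jitter_sd`` adds per-pixel DN jitter to the
    reference levels (the raw cube is built against the jittered
    references, so the round trip still holds).
    """
    r = np.asarray(spectrum, dtype=float)
    if r.shape != (axis.n_bands,):
        raise ValueError("spectrum length must match the axis")
    if np.any(r < 0) or np.any(r > dn_max):
        raise ValueError(f"reflectance must lie in [0, {dn_max}]")
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("cube shape must be positive")
    white_level = float(dn_max) if white_level is None else float(white_level)
    rng = np.random.default_rng(seed)
    wht = np.full((h, w, axis.n_bands), white_level)
    blk = np.full((h, w, axis.n_bands), black_level)
    if jitter_sd > 0:
        wht = wht + rng.normal(0, jitter_sd, wht.shape)
        blk = blk + rng.normal(0, jitter_sd, blk.shape)
    wht = np.clip(np.rint(wht), 0, dn_max)
    blk = np.clip(np.rint(blk), 0, dn_max)
    if np.any(wht - blk <= 0):
        raise ValueError("white reference must exceed black reference everywhere")
    raw = np.rint(blk + (r[None, None, :] / dn_max) * (wht - blk))
    make = lambda d: HyperspectralCube(data=d.astype(np.uint32), axis=axis,
                                       dn_max=dn_max)
    return make(raw), make(wht), make(blk)


# ---------------------------------------------------------------------------
# one-call scenario

def simulate_dataset(seed: int = 0,
                     schedules: Sequence[SamplingSchedule] | None = None,
                     params: TrajectoryParams | None = None,
                     library: PureComponentLibrary | None = None,
                     noise: NoiseModel | None = None,
                     strict: bool = False):
    """Generate the full default scenario: chemistry + spectra.

    Under the default schedules this yields exactly 116 samples x 360
    bands.  Returns ``(ChemistryTable, SpectrumMatrix)``.
    """
    schedules = tuple(schedules) if schedules is not None else default_schedules()
    params = params if params is not None else default_trajectory_params()
    library = library if library is not None else default_library()
    noise = noise if noise is not None else NoiseModel()
    children = np.random.SeedSequence(seed).spawn(len(schedules) + 1)
    tables = [simulate_trajectories(sch, params,
                                    seed=int(children[i].generate_state(1)[0] % (2**31)),
                                    strict=strict)
              for i, sch in enumerate(schedules)]
    chem = ChemistryTable.concat(tables)
    spec_seed = int(children[-1].generate_state(1)[0] % (2**31))
    spectra = synthesize_spectra(chem, library, noise, seed=spec_seed)
    return chem, spectra


def load_scenario(path) -> dict:
    """Read a YAML scenario file into ``simulate_dataset`` keyword args.

    The file must carry an integer ``seed``.  Optional keys: ``replicates``,
    ``n_bands``, and scalar overrides under ``noise`` and
    ``replicate_sd`` / ``measurement_sd``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValueError("scenario file must specify a seed")
    kwargs: dict = {"seed": int(cfg["seed"])}
    axis = SpectralAxis.default(int(cfg.get("n_bands", 360)))
    kwargs["library"] = default_library(axis)
    if "replicates" in cfg:
        kwargs["schedules"] = default_schedules(int(cfg["replicates"]))
    if "noise" in cfg:
        kwargs["noise"] = replace(NoiseModel(), **cfg["noise"])
    params = default_trajectory_params()
    for key in ("replicate_sd", "measurement_sd"):
        if key in cfg:
            getattr(params, key).update({k: float(v) for k, v in cfg[key].items()})
            kwargs["params"] = params
    return kwargs
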