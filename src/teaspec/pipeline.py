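"""End-to-end pipeline: data -> preprocessing -> band selection -> models.

For every analyte x selector x model cell the pipeline

1. splits the samples 4:1 (seeded, once for the whole grid),
2. preprocesses spectra with the configured chain, holding the MSC
   reference at the training-set mean so no test information leaks,
3. selects characteristic bands on the *training* samples only,
4. fits the model on the selected training bands, cross-validates on the
   training set, and evaluates on the held-out samples.

A failing cell is recorded (with its error) and the rest of the grid
proceeds.  Identical config + seed reproduces the grid exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .band_select import BandSelectionResult, SelectorConfig, run_selector
from .containers import ANALYTES, ChemistryTable, SpectrumMatrix
from .model_eval import (EvaluationRow, cross_validate, evaluate,
                         fit_regressor, split_train_test)
from .preprocess import PreprocessConfig, apply_chain, to_absorbance
from .synthetic import simulate_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a grid run needs; all randomness flows from ``seed``."""

    seed: int = 0
    analytes: tuple[str, ...] = ANALYTES
    selectors: tuple[str, ...] = ("spa", "cars", "uve")
    models: tuple[str, ...] = ("pls", "svr", "rf")
    include_all_bands_baseline: bool = False
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    cv_folds: int = 5
    max_components: int = 10
    spectra_csv: str | None = None
    chemistry_csv: str | None = None
    scenario: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    """Grid report plus per-cell artifacts."""

    report: pd.DataFrame
    bands: dict
    scatter: dict
    split: object
    resolved: dict

    def cell(self, analyte: str, selector: str, model: str) -> pd.Series:
        mask = ((self.report["analyte"] == analyte)
                & (self.report["selector"] == selector)
                & (self.report["model"] == model))
        rows = self.report[mask]
        if len(rows) != 1:
            raise KeyError(f"no unique cell ({analyte}, {selector}, {model})")
        return rows.iloc[0]


def _child_seed(root: int, *tags: str) -> int:
    """Stable per-task seed below 2**31 derived from the root seed."""
    h = np.uint64(root)
    for tag in tags:
        for ch in tag:
            h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**63))
    return int(h % (2**31))


def _load_data(config: PipelineConfig):
    if config.spectra_csv and config.chemistry_csv:
        spectra = SpectrumMatrix.from_csv(config.spectra_csv)
        chem = ChemistryTable.from_csv(config.chemistry_csv)
    elif config.spectra_csv or config.chemistry_csv:
        raise ValueError("provide both spectra_csv and chemistry_csv, or neither")
    else:
        chem, spectra = simulate_dataset(
            seed=_child_seed(config.seed, "data"), **config.scenario)
    order = {sid: i for i, sid in enumerate(spectra.sample_ids)}
    missing = [s for s in chem.sample_ids if s not in order]
    if missing or chem.n_samples != spectra.n_samples:
        raise ValueError("chemistry and spectra sample ids do not align")
    chem_sorted = ChemistryTable(
        chem.data.iloc[np.argsort([order[s] for s in chem.sample_ids])]
        .reset_index(drop=True))
    return chem_sorted, spectra


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    chem, spectra = _load_data(config)
    ids = list(spectra.sample_ids)
    split = split_train_test(ids, seed=_child_seed(config.seed, "split"))
    train_idx = np.array([ids.index(s) for s in split.train_ids])
    test_idx = np.array([ids.index(s) for s in split.test_ids])

    # preprocessing; MSC reference frozen at the training-set mean
    msc_ref = None
    if "msc" in config.preprocess.steps:
        base = spectra
        if config.preprocess.domain == "absorbance" and base.domain == "reflectance":
            base = to_absorbance(base, config.preprocess.log_floor)
        msc_ref = base.values[train_idx].mean(axis=0)
    processed = apply_chain(spectra, config.preprocess, msc_reference=msc_ref)
    X = processed.values
    wavelengths = processed.axis.wavelengths

    selectors = tuple(config.selectors)
    if config.include_all_bands_baseline and "none" not in selectors:
        selectors = selectors + ("none",)

    bands: dict = {}
    scatter: dict = {}
    rows = []
    for analyte in config.analytes:
        y = chem.data[analyte].to_numpy(float)
        for selector in selectors:
            key = (analyte, selector)
            try:
                sel = run_selector(selector, X[train_idx], y[train_idx],
                                   config=config.selector,
                                   seed=_child_seed(config.seed, analyte, selector),
                                   wavelengths=wavelengths)
                bands[key] = sel
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                log.warning("selector %s failed for %s: %s", selector, analyte, exc)
                for model in config.models:
                    rows.append({"analyte": analyte, "selector": selector,
                                 "model": model, "error": str(exc)})
                continue
            cols = sel.indices
            Xtr, Xte = X[np.ix_(train_idx, cols)], X[np.ix_(test_idx, cols)]
            for model_family in config.models:
                mseed = _child_seed(config.seed, analyte, selector, model_family)
                try:
                    hp = ({"max_components": config.max_components}
                          if model_family == "pls" else None)
                    model = fit_regressor(model_family, Xtr, y[train_idx],
                                          hyperparams=hp, seed=mseed,
                                          band_indices=cols)
                    rmsecv = cross_validate(model_family, model.hyperparams,
                                            Xtr, y[train_idx],
                                            folds=config.cv_folds, seed=mseed)
                    row = evaluate(model, Xtr, y[train_idx], Xte, y[test_idx],
                                   rmsecv)
                    scatter[(analyte, selector, model_family)] = pd.DataFrame({
                        "sample_id": list(split.test_ids),
                        "actual": y[test_idx],
                        "predicted": model.predict(Xte)})
                    rows.append({"analyte": analyte, "selector": selector,
                                 "model": model_family, **row.as_dict(),
                                 "error": ""})
                except Exception as exc:  # noqa: BLE001
                    log.warning("model %s failed for %s/%s: %s",
                                model_family, analyte, selector, exc)
                    rows.append({"analyte": analyte, "selector": selector,
                                 "model": model_family, "error": str(exc)})
    report = pd.DataFrame(rows)
    resolved = {
        "seed": config.seed,
        "analytes": list(config.analytes),
        "selectors": list(selectors),
        "models": list(config.models),
        "cv_folds": config.cv_folds,
        "max_components": config.max_components,
        "preprocess": {"steps": list(config.preprocess.steps),
                       "window": config.preprocess.window,
                       "polyorder": config.preprocess.polyorder,
                       "domain": config.preprocess.domain},
        "selector_config": {k: v for k, v in asdict(config.selector).items()},
        "n_train": len(split.train_ids), "n_test": len(split.test_ids),
    }
    return PipelineResult(report=report, bands=bands, scatter=scatter,
                          split=split, resolved=resolved)
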