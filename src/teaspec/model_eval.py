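"""Regression models, the train/test split, the evaluation grid and the
withering/fermentation degree judgment.

Model families: PLS (in-repo NIPALS), plus support-vector regression and
random forests behind the same predict contract.  Evaluation follows the
standard calibration/prediction vocabulary of NIR chemometrics:

* ``RC2`` / ``RMSEC`` -- coefficient of determination and RMSE on the
  calibration (training) set,
* ``RMSECV`` -- pooled out-of-fold RMSE under K-fold cross-validation,
* ``RP2`` / ``RMSEP`` -- the same on the held-out prediction set,
* ``RPD = sd(y_test) / RMSEP`` -- relative predictive deviation; a model
  with RPD below 1.4 is flagged as having poor predictive ability.

R-squared is defined as ``1 - SSE/SST`` throughout.

The degree judgment encodes the processing rule: withering is *moderate*
once the free-amino-acid content has plateaued (it peaks at 16 h), and
fermentation once the polyphenol content has plateaued (it bottoms out at
3 h).  A plateau is a trailing window whose spread is a small fraction of
the full series range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .pls import PLSModel, fit_pls, kfold_indices, select_components

__all__ = [
    "SplitSpec", "split_train_test", "RegressionModel", "fit_regressor",
    "cross_validate", "EvaluationRow", "evaluate", "DegreeJudgment",
    "judge_degree", "STAGE_WATCHED", "RPD_POOR_THRESHOLD",
]

#: Component watched for the stage verdict.
STAGE_WATCHED = {"withering": "faa", "fermentation": "tps"}
#: RPD below this indicates poor predictive performance.
RPD_POOR_THRESHOLD = 1.4

# SVR runs on standardised X and y; epsilon is therefore in test-SD units
_DEFAULT_SVR = {"kernel": "rbf", "C": 10.0, "gamma": "scale", "epsilon": 0.1}
_DEFAULT_RF = {"n_estimators": 300, "max_depth": None, "max_features": 1.0}


# ---------------------------------------------------------------------------
# split

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test sample-id lists from a seeded 4:1 split."""

    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def split_train_test(sample_ids, seed: int = 0) -> SplitSpec:
    """Uniform random 4:1 split; test size is ``round(n / 5)``."""
    ids = list(sample_ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 samples for a 4:1 split")
    n_test = int(round(n / 5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = sorted(perm[:n_test])
    train = sorted(perm[n_test:])
    return SplitSpec(train_ids=tuple(ids[i] for i in train),
                     test_ids=tuple(ids[i] for i in test), seed=seed)


# ---------------------------------------------------------------------------
# models

FAMILIES = ("pls", "svr", "rf")


@dataclass
class RegressionModel:
    """Fitted model honouring a single predict contract."""

    family: str
    impl: object
    n_features: int
    band_indices: np.ndarray | None = None
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"model was trained on {self.n_features} bands, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}")
        if isinstance(self.impl, PLSModel):
            return self.impl.predict(X)
        return np.asarray(self.impl.predict(X), dtype=float)


def fit_regressor(family: str, X: np.ndarray, y: np.ndarray,
                  hyperparams: dict | None = None, seed: int = 0,
                  band_indices=None) -> RegressionModel:
    """Fit one model family.

    PLS accepts ``n_components`` (int, or ``"auto"`` for inner 5-fold CV
    up to ``max_components``); SVR takes the usual kernel/C/epsilon knobs
    (features are standardised inside the model); RF takes
    trees/depth/features-per-split and is reproducible under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    hp = dict(hyperparams or {})
    if family == "pls":
        n_comp = hp.pop("n_components", "auto")
        max_comp = hp.pop("max_components", 10)
        if hp:
            raise ValueError(f"unknown PLS hyperparameters: {sorted(hp)}")
        if n_comp == "auto":
            n_comp = select_components(
                X, y, min(max_comp, X.shape[0] - 2, X.shape[1]), seed=seed)
        impl: object = fit_pls(X, y, int(n_comp))
        hp = {"n_components": int(n_comp)}
    elif family == "svr":
        params = {**_DEFAULT_SVR, **hp}
        impl = TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), SVR(**params)),
            transformer=StandardScaler())
        impl.fit(X, y)
        hp = params
    elif family == "rf":
        params = {**_DEFAULT_RF, **hp}
        impl = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        impl.fit(X, y)
        hp = params
    else:
        raise ValueError(f"unknown model family: {family!r} (known: {FAMILIES})")
    return RegressionModel(family=family, impl=impl, n_features=X.shape[1],
                           band_indices=None if band_indices is None
                           else np.asarray(band_indices, dtype=int),
                           hyperparams=hp)


def cross_validate(family: str, hyperparams: dict | None, X: np.ndarray,
                   y: np.ndarray, folds: int = 5, seed: int = 0) -> float:
    """Seeded K-fold RMSECV: out-of-fold predictions pooled, then RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    sq = 0.0
    for test in kfold_indices(n, folds, seed):
        if test.size < 1:
            raise ValueError("cross-validation fold with no samples")
        train = np.setdiff1d(np.arange(n), test)
        model = fit_regressor(family, X[train], y[train],
                              hyperparams=hyperparams, seed=seed)
        err = model.predict(X[test]) - y[test]
        sq += float(err @ err)
    return float(np.sqrt(sq / n))


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationRow:
    """One cell of the analyte x selector x model grid."""

    rc2: float
    rmsec: float
    rmsecv: float
    rp2: float
    rmsep: float
    rpd: float
    n_bands: int
    flag: str = "ok"          # "ok" | "poor" | "undefined"

    def as_dict(self) -> dict:
        return {"rc2": self.rc2, "rmsec": self.rmsec, "rmsecv": self.rmsecv,
                "rp2": self.rp2, "rmsep": self.rmsep, "rpd": self.rpd,
                "n_bands": self.n_bands, "flag": self.flag}


def _r2(y, pred) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan


def evaluate(model: RegressionModel, X_train, y_train, X_test, y_test,
             rmsecv: float) -> EvaluationRow:
    """Score a fitted model on calibration and prediction sets."""
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    pred_train = model.predict(np.asarray(X_train, dtype=float))
    pred_test = model.predict(np.asarray(X_test, dtype=float))
    rmsec = float(np.sqrt(np.mean((pred_train - y_train) ** 2)))
    rmsep = float(np.sqrt(np.mean((pred_test - y_test) ** 2)))
    sd_test = float(np.std(y_test, ddof=1)) if y_test.size > 1 else 0.0
    # an exact fit leaves only float dust in rmsep; RPD is then meaningless
    if rmsep <= 1e-12 * max(sd_test, 1.0) or sd_test == 0:
        rpd, flag = np.nan, "undefined"
    else:
        rpd = sd_test / rmsep
        flag = "poor" if rpd < RPD_POOR_THRESHOLD else "ok"
    return EvaluationRow(rc2=_r2(y_train, pred_train), rmsec=rmsec,
                         rmsecv=float(rmsecv), rp2=_r2(y_test, pred_test),
                         rmsep=rmsep, rpd=float(rpd), n_bands=model.n_features,
                         flag=flag)


# ---------------------------------------------------------------------------
# degree judgment

@dataclass
class DegreeJudgment:
    """Plateau-based stage verdict.

    ``verdicts[i]`` is True from the first time point whose trailing
    window is stable; ``detected_at`` is that time point and
    ``plateau_onset_h`` the start of the stable window (the plateau's
    beginning).  Once moderate, the verdict stays moderate.
    """

    stage: str
    analyte: str
    times: np.ndarray
    verdicts: np.ndarray
    detected_at: float | None
    plateau_onset_h: float | None
    window: int
    tolerance: float


def judge_degree(series, times=None, stage: str = "withering",
                 window: int = 3, tolerance: float = 0.05) -> DegreeJudgment:
    """Judge processing degree from a content series over time.

    The watched component is FAA for withering and TPs for fermentation.
    A time point is *moderate* when, over the trailing ``window`` points,
    ``max - min <= tolerance * (overall series range)``; for a constant
    series every full window qualifies.
    """
    if stage not in STAGE_WATCHED:
        raise ValueError(f"stage must be one of {sorted(STAGE_WATCHED)}")
    y = np.asarray(series, dtype=float).ravel()
    t = (np.arange(1, y.size + 1, dtype=float) if times is None
         else np.asarray(times, dtype=float).ravel())
    if t.size != y.size:
        raise ValueError("times and series lengths differ")
    if window < 1 or window > y.size:
        raise ValueError(f"window must lie in [1, {y.size}]")
    full_range = float(np.ptp(y))
    verdicts = np.zeros(y.size, dtype=bool)
    detected = None
    for i in range(window - 1, y.size):
        w = y[i - window + 1: i + 1]
        if float(np.ptp(w)) <= tolerance * full_range:
            detected = i
            break
    if detected is not None:
        verdicts[detected:] = True
        return DegreeJudgment(stage=stage, analyte=STAGE_WATCHED[stage],
                              times=t, verdicts=verdicts,
                              detected_at=float(t[detected]),
                              plateau_onset_h=float(t[detected - window + 1]),
                              window=window, tolerance=tolerance)
    return DegreeJudgment(stage=stage, analyte=STAGE_WATCHED[stage], times=t,
                          verdicts=verdicts, detected_at=None,
                          plateau_onset_h=None, window=window,
                          tolerance=tolerance)
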