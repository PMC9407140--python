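"""Characteristic-band selection: SPA, CARS and UVE.

Three classical chemometric wavelength selectors, each returning the
retained band indices plus method-specific diagnostics:

* **SPA** (successive projections algorithm) greedily grows chains of
  minimally collinear bands -- at every step it picks the band with the
  largest norm after projecting out the span of the bands already chosen
  -- and scores every (start band, chain length) candidate by K-fold
  RMSECV of an ordinary least-squares fit.
* **CARS** (competitive adaptive reweighted sampling) runs Monte Carlo
  PLS fits on random sample subsets, keeps the bands with the largest
  absolute regression coefficients under an exponentially decreasing
  retention schedule, resamples survivors with probability proportional
  to coefficient magnitude, and returns the run whose survivor set has
  the smallest cross-validated RMSE.
* **UVE** (uninformative variable elimination) appends tiny-amplitude
  random noise bands, fits PLS across a cross-validation scheme, forms
  the stability ``c_j = mean(b_j) / sd(b_j)`` of every coefficient, and
  retains the real bands whose |stability| exceeds a high percentile of
  the noise-band stabilities.

The original methods publications leave most constants free; the defaults
here (50 Monte Carlo runs, 0.8 sampling fraction, 5-fold CV, 99th
percentile cutoff, SPA sizes 5-30) follow common practice and are all
exposed on :class:`SelectorConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .pls import fit_pls, kfold_indices, pls_rmsecv, select_components

log = logging.getLogger(__name__)

__all__ = ["SelectorConfig", "BandSelectionResult", "spa", "cars", "uve",
           "cars_retention_schedule", "run_selector"]


@dataclass(frozen=True)
class SelectorConfig:
    """Shared configuration of the three selectors."""

    spa_size_min: int = 5
    spa_size_max: int = 30
    cv_folds: int = 5
    max_latent: int = 10
    cars_runs: int = 50
    cars_fraction: float = 0.8
    cars_ars: bool = True
    uve_n_noise: int | None = None          # default: one per real band
    uve_noise_amplitude: float = 1e-10
    uve_percentile: float = 99.0
    uve_cv: str | int = "loo"

    def __post_init__(self) -> None:
        if self.spa_size_min < 1 or self.spa_size_max < self.spa_size_min:
            raise ValueError("SPA size range invalid")
        if self.cv_folds < 2 or self.cars_runs < 2 or self.max_latent < 1:
            raise ValueError("counts must be positive (folds/runs >= 2)")
        if not 0 < self.cars_fraction < 1:
            raise ValueError("CARS sampling fraction must lie in (0, 1)")
        if not 50 < self.uve_percentile <= 100:
            raise ValueError("UVE percentile must lie in (50, 100]")


@dataclass
class BandSelectionResult:
    """Selected bands plus diagnostics of the selection run."""

    method: str
    indices: np.ndarray
    wavelengths: np.ndarray
    diagnostics: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size < 1:
            raise ValueError("a selection must retain at least one band")
        if np.unique(idx).size != idx.size:
            raise ValueError("selected indices must be unique")
        order = np.argsort(idx)
        self.indices = idx[order]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)[order]

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def format_ranges(self) -> str:
        """Table-style summary: contiguous index runs as wavelength ranges,
        e.g. ``519-522, 653, 733``."""
        parts = []
        start = prev = self.indices[0]
        wl = {int(i): w for i, w in zip(self.indices, self.wavelengths)}
        for i in self.indices[1:]:
            if i == prev + 1:
                prev = i
                continue
            parts.append((start, prev))
            start = prev = i
        parts.append((start, prev))
        out = []
        for a, b in parts:
            if a == b:
                out.append(f"{wl[int(a)]:.0f}")
            else:
                out.append(f"{wl[int(a)]:.0f}-{wl[int(b)]:.0f}")
        return ", ".join(out)

    def to_dict(self) -> dict:
        diag = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()}
        return {"method": self.method,
                "n_selected": self.n_selected,
                "indices": self.indices.tolist(),
                "wavelengths": [round(float(w), 2) for w in self.wavelengths],
                "ranges": self.format_ranges(),
                "diagnostics": diag}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _wavelengths_for(indices, wavelengths, p):
    if wavelengths is None:
        return np.asarray(indices, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != p:
        raise ValueError("wavelength vector length must match band count")
    return wavelengths[np.asarray(indices, dtype=int)]


# ---------------------------------------------------------------------------
# SPA

def spa_chain(X: np.ndarray, start: int, length: int,
              tol: float = 1e-9) -> np.ndarray:
    """One successive-projections chain from a given start column.

    Columns are mean-centered; at each step the unpicked column with the
    largest residual norm (after projecting out the picked columns) is
    added.  The chain is truncated, with a log note, if every residual
    norm collapses (rank deficiency).
    """
    Xc = X - X.mean(axis=0)
    n, p = Xc.shape
    scale = float(np.linalg.norm(Xc)) or 1.0
    R = Xc.copy()
    picked = [int(start)]
    for _ in range(1, min(length, p)):
        u = R[:, picked[-1]].copy()
        nu = np.linalg.norm(u)
        if nu <= tol * scale:
            log.info("SPA chain from %d truncated at %d bands (rank deficiency)",
                     start, len(picked))
            break
        u /= nu
        R -= np.outer(u, u @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[picked] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol * scale:
            log.info("SPA chain from %d truncated at %d bands (rank deficiency)",
                     start, len(picked))
            break
        picked.append(nxt)
    return np.array(picked, dtype=int)


def _ols_prefix_rmsecv(X, y, chains, m_min, m_max, folds, seed):
    """RMSECV of OLS on every chain prefix, via one QR per (chain, fold).

    All prefix predictions are obtained at once: with ``M = Q R`` on the
    training rows, ``pred_m(test) = cumsum(M_test R^{-1} * (Q^T y))`` up to
    column ``m``.  Returns an array ``rmse[start, m]`` (inf where a prefix
    is rank deficient in some fold).
    """
    n, p = X.shape
    fold_idx = kfold_indices(n, folds, seed)
    train_idx = [np.setdiff1d(np.arange(n), t) for t in fold_idx]
    sq = np.zeros((len(chains), m_max + 1))
    ok = np.ones((len(chains), m_max + 1), dtype=bool)
    ones = np.ones((n, 1))
    col_scale = max(float(np.abs(X).max()), 1.0)
    for ci, chain in enumerate(chains):
        M = np.hstack([ones, X[:, chain]])
        top = min(m_max, chain.size)
        for test, train in zip(fold_idx, train_idx):
            Q, Rf = np.linalg.qr(M[train][:, :top + 1])
            qty = Q.T @ y[train]
            diag = np.abs(np.diag(Rf))
            bad = diag < 1e-12 * col_scale
            if bad.any():
                first_bad = int(np.argmax(bad))
                ok[ci, first_bad:] = False
            Rinv = solve_triangular(Rf, np.eye(top + 1))
            contrib = (M[test][:, :top + 1] @ Rinv) * qty[None, :]
            preds = np.cumsum(contrib, axis=1)          # (n_test, top+1)
            err = preds - y[test][:, None]
            sq[ci, :top + 1] += np.sum(err ** 2, axis=0)
        sq[ci, top + 1:] = np.inf
        ok[ci, top + 1:] = False
    with np.errstate(invalid="ignore"):
        rmse = np.sqrt(sq / n)
    rmse[~ok] = np.inf
    rmse[:, :m_min] = np.inf
    return rmse


def spa(X: np.ndarray, y: np.ndarray, config: SelectorConfig | None = None,
        seed: int = 0, wavelengths: np.ndarray | None = None) -> BandSelectionResult:
    """Successive projections algorithm over all start bands.

    Every (start band, size) chain within the configured size range is
    scored by K-fold RMSECV of least squares; the minimum wins, with ties
    broken toward smaller size, then smaller start index.  The size range
    is clamped to the available band count when necessary.
    """
    config = config or SelectorConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < config.cv_folds:
        raise ValueError("need at least as many samples as CV folds")
    m_max = min(config.spa_size_max, p, n - 2)
    m_min = min(config.spa_size_min, m_max)
    if m_max < config.spa_size_max:
        log.info("SPA size range clamped to [%d, %d] (p=%d, n=%d)",
                 m_min, m_max, p, n)
    chains = [spa_chain(X, j, m_max) for j in range(p)]
    rmse = _ols_prefix_rmsecv(X, y, chains, m_min, m_max, config.cv_folds, seed)
    best = (np.inf, -1, -1)
    for m in range(m_min, m_max + 1):
        for j in range(p):
            if rmse[j, m] < best[0]:
                best = (float(rmse[j, m]), m, j)
    if best[2] < 0:
        raise ValueError("SPA could not evaluate any candidate chain")
    score, m, j = best
    indices = np.sort(chains[j][:m])
    return BandSelectionResult(
        method="spa", indices=indices,
        wavelengths=_wavelengths_for(indices, wavelengths, p),
        diagnostics={"rmsecv": score, "best_start": j, "best_size": m,
                     "per_start_best": np.min(rmse, axis=1)})


# ---------------------------------------------------------------------------
# CARS

def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retained-band counts, run 1 -> p, run N -> 2.

    ``r_i = a * exp(-k i)`` with ``a = (p/2)^(1/(N-1))`` and
    ``k = ln(p/2) / (N-1)``; the count at run ``i`` is ``ceil(p * r_i)``.
    """
    if p < 2 or n_runs < 2:
        raise ValueError("schedule needs p >= 2 and n_runs >= 2")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    # guard against float dust pushing an exact count over the next integer
    counts = np.ceil(p * a * np.exp(-k * i) - 1e-9).astype(int)
    return np.clip(counts, 2, p)


def cars(X: np.ndarray, y: np.ndarray, config: SelectorConfig | None = None,
         seed: int = 0, wavelengths: np.ndarray | None = None) -> BandSelectionResult:
    """Competitive adaptive reweighted sampling."""
    config = config or SelectorConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least two bands")
    if n < config.cv_folds:
        raise ValueError("need at least as many samples as CV folds")
    rng = np.random.default_rng(seed)
    schedule = cars_retention_schedule(p, config.cars_runs)
    n_comp = select_components(X, y, min(config.max_latent, n - 2, p),
                               folds=config.cv_folds, seed=seed)
    n_sub = max(int(np.ceil(config.cars_fraction * n)), n_comp + 2)
    retained = np.arange(p)
    best: tuple[float, int, np.ndarray] | None = None
    trace_rmsecv, trace_counts = [], []
    for i in range(config.cars_runs):
        subset = rng.choice(n, size=min(n_sub, n), replace=False)
        a = min(n_comp, retained.size, subset.size - 1)
        model = fit_pls(X[np.ix_(subset, retained)], y[subset], a)
        weight = np.abs(model.coef)
        order = np.argsort(-weight, kind="stable")
        keep = min(int(schedule[i]), retained.size)
        top = order[:keep]
        survivors = retained[top]
        if config.cars_ars and weight[top].sum() > 0:
            # p weighted draws with replacement; unique survivors kept.  The
            # draw count equals the full band count so the EDF schedule, not
            # the resampling, controls the contraction rate.
            probs = weight[top] / weight[top].sum()
            draws = rng.choice(survivors, size=p, replace=True, p=probs)
            survivors = np.unique(draws)
        else:
            survivors = np.sort(survivors)
        if survivors.size < 2:
            log.info("CARS stopped at run %d: survivor set collapsed", i + 1)
            if survivors.size == 0:
                break
        a_eval = min(n_comp, survivors.size, n - 1 - int(np.ceil(n / config.cv_folds)))
        a_eval = max(a_eval, 1)
        rmsecv = pls_rmsecv(X[:, survivors], y, a_eval,
                            folds=config.cv_folds, seed=seed)
        trace_rmsecv.append(rmsecv)
        trace_counts.append(int(survivors.size))
        if (best is None or rmsecv < best[0]
                or (rmsecv == best[0] and survivors.size < best[1])):
            best = (rmsecv, int(survivors.size), survivors.copy())
        retained = survivors
        if retained.size < 2:
            break
    if best is None:
        raise ValueError("CARS produced no evaluable survivor set")
    indices = np.sort(best[2])
    return BandSelectionResult(
        method="cars", indices=indices,
        wavelengths=_wavelengths_for(indices, wavelengths, p),
        diagnostics={"rmsecv_trace": np.array(trace_rmsecv),
                     "count_trace": np.array(trace_counts),
                     "schedule": schedule, "rmsecv": best[0],
                     "n_components": n_comp})


# ---------------------------------------------------------------------------
# UVE

def uve(X: np.ndarray, y: np.ndarray, config: SelectorConfig | None = None,
        seed: int = 0, wavelengths: np.ndarray | None = None) -> BandSelectionResult:
    """Uninformative variable elimination against appended noise bands.

    Only real bands can be retained: the cutoff is a percentile of the
    noise-band stabilities, and noise bands are dropped by construction.
    """
    config = config or SelectorConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("UVE needs at least three samples")
    rng = np.random.default_rng(seed)
    k = config.uve_n_noise if config.uve_n_noise is not None else p
    noise_block = rng.uniform(size=(n, k)) * config.uve_noise_amplitude
    Xa = np.hstack([X, noise_block])
    n_comp = select_components(X, y, min(config.max_latent, n - 2, p),
                               folds=config.cv_folds, seed=seed)
    if config.uve_cv == "loo":
        folds = [np.array([i]) for i in range(n)]
    else:
        folds = kfold_indices(n, int(config.uve_cv), seed)
    coefs = np.zeros((len(folds), p + k))
    for fi, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        a = min(n_comp, train.size - 1, p + k)
        coefs[fi] = fit_pls(Xa[train], y[train], a).coef
    mean_b = coefs.mean(axis=0)
    sd_b = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = mean_b / sd_b
    degenerate = sd_b == 0
    if degenerate.any():
        log.info("UVE: %d coefficients with zero fold variance",
                 int(degenerate.sum()))
        stability[degenerate] = np.where(mean_b[degenerate] == 0, 0.0,
                                         np.sign(mean_b[degenerate]) * np.inf)
    abs_stab = np.abs(stability)
    cutoff = float(np.percentile(abs_stab[p:], config.uve_percentile))
    retained = np.flatnonzero(abs_stab[:p] > cutoff)
    if retained.size == 0:
        retained = np.array([int(np.argmax(abs_stab[:p]))])
        log.info("UVE: no band exceeded the cutoff; keeping the most stable one")
    return BandSelectionResult(
        method="uve", indices=retained,
        wavelengths=_wavelengths_for(retained, wavelengths, p),
        diagnostics={"stability": stability[:p],
                     "noise_stability": stability[p:],
                     "cutoff": cutoff, "n_components": n_comp})


_SELECTORS = {"spa": spa, "cars": cars, "uve": uve}


def run_selector(name: str, X, y, config: SelectorConfig | None = None,
                 seed: int = 0, wavelengths=None) -> BandSelectionResult:
    """Dispatch by selector name; ``"none"`` returns the all-bands baseline."""
    if name == "none":
        p = np.asarray(X).shape[1]
        idx = np.arange(p)
        return BandSelectionResult(method="none", indices=idx,
                                   wavelengths=_wavelengths_for(idx, wavelengths, p))
    if name not in _SELECTORS:
        raise ValueError(f"unknown selector: {name!r} "
                         f"(known: {sorted(_SELECTORS)} + 'none')")
    return _SELECTORS[name](X, y, config=config, seed=seed,
                            wavelengths=wavelengths)
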