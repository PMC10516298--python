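"""Partial least squares estimation of clinical outcomes.

PLS1 (univariate response) regression with

* cross-validated selection of the number of latent variables (5-fold,
  MSE-minimizing, ties broken toward fewer components),
* exhaustive subset search over oculomotor parameters (age always kept
  as a fixed covariate), complete cases scoped per candidate subset,
* standardized coefficients beta_std = b * sd(x) / sd(y) and their
  normalized absolute values as contribution weights.

The PLS1 core is a compact NIPALS implementation: the search evaluates
tens of thousands of fits per run, so per-fit overhead matters.  With
as many components as full-rank predictors it reproduces ordinary
least squares, which the tests exploit as a closed-form oracle (and
cross-check against scikit-learn's PLSRegression).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

_EPS = 1e-12


class ZeroVarianceFeatureError(ValueError):
    pass


def _standardize(X: np.ndarray, names=None):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if not np.isfinite(s) or s <= 0:
            name = names[j] if names is not None else f"column {j}"
            raise ZeroVarianceFeatureError(f"zero-variance feature {name!r}")
    return (X - mean) / sd, mean, sd


def _pls1_coef_path(Xs: np.ndarray, ys: np.ndarray,
                    max_components: int) -> list[np.ndarray]:
    """NIPALS PLS1 on standardized data; coefficient vector per 1..K."""
    n, p = Xs.shape
    Xk = Xs.copy()
    yk = ys.copy()
    W, P, Q = [], [], []
    paths: list[np.ndarray] = []
    for _ in range(min(max_components, p)):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pvec = Xk.T @ t / tt
        q = float(yk @ t) / tt
        Xk -= np.outer(t, pvec)
        yk = yk - q * t
        W.append(w)
        P.append(pvec)
        Q.append(q)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        # B = W (P'W)^-1 q   (coefficients in standardized space)
        coef = Wm @ np.linalg.solve(Pm.T @ Wm, np.asarray(Q))
        paths.append(coef)
    if not paths:  # degenerate y (e.g. constant): zero model
        paths = [np.zeros(p)]
    return paths


@dataclass
class PLSModel:
    """Fitted PLS1 regression in original units."""

    coef_: np.ndarray          # original-unit slopes, one per feature
    intercept_: float
    n_components: int
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.coef_ + self.intercept_


def fit_pls(X, y, n_components: int, feature_names=None) -> PLSModel:
    """Fit PLS1 with internally standardized columns.

    With ``n_components == rank(X)`` the coefficients equal OLS.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n_components < 1 or n_components > p:
        raise ValueError("n_components must be in [1, n_features]")
    names = list(feature_names) if feature_names is not None \
        else [f"x{j}" for j in range(p)]
    Xs, x_mean, x_sd = _standardize(X, names)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    ys = (y - y_mean) / y_sd if y_sd > 0 else y - y_mean
    paths = _pls1_coef_path(Xs, ys, n_components)
    coef_std = paths[min(n_components, len(paths)) - 1]
    scale = y_sd if y_sd > 0 else 1.0
    coef = scale * coef_std / x_sd
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(coef_=coef, intercept_=intercept,
                    n_components=n_components, feature_names=names,
                    x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd)


def _max_components(n: int, p: int, folds: int) -> int:
    return max(1, min(p, n - int(np.ceil(n / folds)) - 1))


def select_components_cv(X, y, folds: int = 5, seed: int = 0,
                         max_components: int | None = None) -> int:
    """Latent-variable count minimizing k-fold CV MSE (ties -> fewer)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    kmax = _max_components(n, p, folds) if max_components is None \
        else min(max_components, p)
    mse = _cv_mse_path(X, y, kmax, folds, seed)
    return int(np.argmin(mse)) + 1


def _cv_mse_path(X: np.ndarray, y: np.ndarray, kmax: int,
                 folds: int, seed: int) -> np.ndarray:
    """CV MSE for each component count 1..kmax (one PLS path per fold)."""
    n, p = X.shape
    sq_err = np.zeros(kmax)
    counts = np.zeros(kmax)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        Xtr, ytr = X[train], y[train]
        sd = Xtr.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            continue
        Xs = (Xtr[:, keep] - Xtr[:, keep].mean(0)) / sd[keep]
        y_mean, y_sd = ytr.mean(), ytr.std(ddof=1)
        ys = (ytr - y_mean) / y_sd if y_sd > 0 else ytr - y_mean
        paths = _pls1_coef_path(Xs, ys, kmax)
        scale = y_sd if y_sd > 0 else 1.0
        # original-unit coefficient matrix, one column per component count
        C = np.column_stack([paths[min(k, len(paths) - 1)]
                             for k in range(kmax)]) * scale / sd[keep, None]
        icpt = y_mean - Xtr[:, keep].mean(0) @ C
        preds = X[test][:, keep] @ C + icpt
        sq_err += np.sum((y[test, None] - preds) ** 2, axis=0)
        counts += len(test)
    return sq_err / np.maximum(counts, 1)


def cv_r2(X, y, n_components: int, folds: int = 5, seed: int = 0) -> float:
    """k-fold cross-validated R^2 of a PLS fit with fixed components."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    mse = _cv_mse_path(X, y, n_components, folds, seed)[n_components - 1]
    denom = float(np.var(y))
    return 1.0 - mse / denom if denom > 0 else float("nan")


def standardized_coefficients(model: PLSModel, X, y) \
        -> tuple[np.ndarray, np.ndarray]:
    """beta_std = b * sd(x)/sd(y); contributions = |beta_std| normalized."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    sd_y = float(y.std(ddof=1))
    if sd_y == 0:
        raise ValueError("outcome has zero variance")
    beta_std = model.coef_ * X.std(axis=0, ddof=1) / sd_y
    total = float(np.sum(np.abs(beta_std)))
    contrib = np.abs(beta_std) / total if total > 0 \
        else np.full_like(beta_std, np.nan)
    return beta_std, contrib


@dataclass(frozen=True)
class SearchSettings:
    """Feature-search configuration for one outcome model."""

    pool: tuple[str, ...] | None = None   # None -> all profile columns
    min_size: int = 1
    max_size: int | None = None           # None -> pool size (mode-capped)
    mode: str = "capped"                  # exhaustive | capped | greedy
    cap_size: int = 8
    folds: int = 5
    seed: int = 0
    metric: str = "r2"                    # r2 | adj_r2

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("fold count must be >= 2")
        if self.mode not in ("exhaustive", "capped", "greedy"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.metric not in ("r2", "adj_r2"):
            raise ValueError(f"unknown selection metric {self.metric!r}")


@dataclass
class PLSResult:
    outcome: str
    features: list[str]            # selected oculomotor parameters (age excluded)
    covariates: list[str]          # always-included covariates (age)
    n_components: int
    coefficients: dict
    intercept: float
    beta_std: dict
    contributions: dict
    r2: float
    adj_r2: float
    cv_r2: float
    n_used: int
    predictions: pd.DataFrame      # observed vs fitted, complete cases
    search_log: list = field(default_factory=list)
    exhaustive: bool = True

    def to_report(self) -> dict:
        return {
            "outcome": self.outcome, "features": self.features,
            "covariates": self.covariates,
            "n_components": self.n_components,
            "coefficients": self.coefficients, "intercept": self.intercept,
            "beta_std": self.beta_std, "contributions": self.contributions,
            "r2": self.r2, "adj_r2": self.adj_r2, "cv_r2": self.cv_r2,
            "n_used": self.n_used, "exhaustive_search": self.exhaustive,
        }


def adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


class _SearchData:
    """Numpy view of the search table (pandas is too slow per subset)."""

    def __init__(self, data: pd.DataFrame, outcome: str):
        self.columns = list(data.columns)
        self.col_idx = {c: j for j, c in enumerate(self.columns)}
        self.M = data.to_numpy(float)
        self.finite = np.isfinite(self.M)
        self.y_col = self.col_idx[outcome]
        self.index = data.index


def _score_subset(sd: _SearchData, subset: list[str], covars: list[str],
                  settings: SearchSettings):
    cols = list(subset) + covars
    jx = [sd.col_idx[c] for c in cols]
    rows = sd.finite[:, jx].all(axis=1) & sd.finite[:, sd.y_col]
    n, p = int(rows.sum()), len(cols)
    if n <= p + 1 or n < settings.folds:
        return None
    X = sd.M[np.ix_(rows, jx)]
    y = sd.M[rows, sd.y_col]
    if np.any(X.std(axis=0, ddof=1) <= 0) or y.std(ddof=1) <= 0:
        return None
    ncomp = select_components_cv(X, y, folds=settings.folds,
                                 seed=settings.seed)
    model = fit_pls(X, y, ncomp, feature_names=cols)
    pred = model.predict(X)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    score = adjusted_r2(r2, n, p) if settings.metric == "adj_r2" else r2
    return dict(model=model, r2=r2, score=score, ncomp=ncomp, n=n,
                index=sd.index[rows], X=X, y=y, pred=pred, cols=cols)


def exhaustive_feature_selection(profiles: pd.DataFrame, outcome_values,
                                 outcome_name: str,
                                 settings: SearchSettings = SearchSettings(),
                                 covariates: pd.DataFrame | None = None) \
        -> PLSResult:
    """Search oculomotor-parameter subsets for the best PLS model.

    Every candidate subset is augmented with the covariates (age),
    restricted to its own complete cases, its component count chosen by
    CV, and scored by (in-sample) R^2.  ``mode='exhaustive'`` visits
    all subset sizes; 'capped' truncates at ``cap_size`` (warning
    logged); 'greedy' is forward selection.
    """
    pool = list(settings.pool) if settings.pool is not None \
        else list(profiles.columns)
    unknown = set(pool) - set(profiles.columns)
    if unknown:
        raise ValueError(f"unknown parameters in pool: {sorted(unknown)}")
    data = profiles.copy()
    covar_names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            data[c] = np.asarray(covariates[c], float)
            covar_names.append(c)
    data[outcome_name] = np.asarray(outcome_values, float)

    max_size = settings.max_size if settings.max_size is not None else len(pool)
    exhaustive = True
    if settings.mode == "capped" and max_size > settings.cap_size:
        max_size = settings.cap_size
        exhaustive = False
        msg = (f"subset search for {outcome_name!r} capped at size "
               f"{settings.cap_size} of {len(pool)} parameters; "
               f"search is not fully exhaustive")
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)

    best = None
    best_subset: list[str] = []
    search_log: list[tuple[tuple[str, ...], float]] = []
    sdata = _SearchData(data, outcome_name)

    def consider(subset: list[str]):
        nonlocal best, best_subset
        res = _score_subset(sdata, subset, covar_names, settings)
        if res is None:
            return None
        search_log.append((tuple(subset), res["score"]))
        if best is None or res["score"] > best["score"] + 1e-12:
            best, best_subset = res, list(subset)
        return res

    if settings.mode in ("exhaustive", "capped"):
        for size in range(settings.min_size, max_size + 1):
            for subset in itertools.combinations(pool, size):
                consider(list(subset))
    else:  # greedy forward
        exhaustive = False
        log.warning("greedy forward search for %r; not exhaustive",
                    outcome_name)
        current: list[str] = []
        remaining = list(pool)
        while remaining and len(current) < max_size:
            scored = [(consider(current + [f]), f) for f in remaining]
            scored = [(r, f) for r, f in scored if r is not None]
            if not scored:
                break
            _, best_f = max(scored, key=lambda t: t[0]["score"])
            current.append(best_f)
            remaining.remove(best_f)

    if best is None:
        raise ValueError(
            f"no candidate subset for {outcome_name!r} has enough "
            "complete cases")

    model = best["model"]
    beta_std, contrib = standardized_coefficients(model, best["X"], best["y"])
    preds = pd.DataFrame({"observed": best["y"], "predicted": best["pred"]},
                         index=best["index"])
    return PLSResult(
        outcome=outcome_name, features=best_subset, covariates=covar_names,
        n_components=best["ncomp"],
        coefficients=dict(zip(best["cols"], model.coef_.tolist())),
        intercept=model.intercept_,
        beta_std=dict(zip(best["cols"], beta_std.tolist())),
        contributions=dict(zip(best["cols"], contrib.tolist())),
        r2=best["r2"], adj_r2=adjusted_r2(best["r2"], best["n"],
                                          len(best["cols"])),
        cv_r2=cv_r2(best["X"], best["y"], best["ncomp"],
                    folds=settings.folds, seed=settings.seed),
        n_used=best["n"], predictions=preds, search_log=search_log,
        exhaustive=exhaustive)
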