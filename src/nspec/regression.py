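"""Multivariate calibration engines with cross-validated order selection.

Four methods relate a samples x bands spectral matrix to leaf N (%):

- MLR: ordinary least squares; on p >> n spectral data the normal
  equations are singular, so the minimum-norm (pseudoinverse) solution is
  used — the fit interpolates the calibration set and any degradation
  shows up in validation, which is exactly how full-spectrum MLR behaves
  in this literature.
- PCR: principal component regression; components ordered by explained
  predictor variance, response regressed on the leading k scores, k chosen
  at minimum RMSECV.
- PLS: NIPALS PLS1.  Per component: weight w proportional to X'y (unit
  norm), scores t = Xw, x-loading p = X't/t't, y-loading q = y't/t't,
  rank-one deflation of X.  Deflating y is unnecessary for a single
  response (the scores are mutually orthogonal), so only X is deflated.
  The number of latent variables is chosen at minimum RMSECV.
- SVM: epsilon-SVR with a Gaussian RBF kernel exp(-g * ||u - v||^2);
  predictors are z-score standardized internally; (c, g, epsilon) chosen
  by minimum RMSECV over a Cartesian grid (half-decade log spacing by
  default, so g = 3.16 = 10^0.5 is representable).

Cross-validation is leave-one-out by default for PCR/PLS order selection
and seeded 10-fold for the SVR grid (a grid search multiplies the fold
cost by the grid size, and 10-fold is the standard chemometrics choice
there).  RMSECV ties break toward the smaller model order (parsimony).
Mean-centering only (no autoscaling) for MLR/PCR/PLS: all bands share
reflectance units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
from sklearn.svm import SVR

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    ShapeError,
    SizeError,
)

METHODS = ("MLR", "PCR", "PLS", "SVM")

#: Default epsilon-SVR grid: half-decade log spacing.
DEFAULT_SVR_GRID: dict[str, tuple[float, ...]] = {
    "c": tuple(float(v) for v in 10.0 ** (np.arange(-4, 7) / 2.0)),       # 1e-2 .. 1e3
    "g": tuple(float(v) for v in 10.0 ** (np.arange(-4, 5) / 2.0)),       # 1e-2 .. 1e2
    "epsilon": (0.01, 0.1, 0.5),
}


# -- cross-validation schemes ---------------------------------------------

@dataclass(frozen=True)
class CVScheme:
    """Leave-one-out or seeded k-fold cross-validation."""

    kind: str = "loo"
    k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loo", "kfold"):
            raise ConfigurationError(f"unknown cv kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ConfigurationError("k-fold needs k >= 2")

    def folds(self, n: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        if self.kind == "loo":
            idx = np.arange(n)
            for i in range(n):
                yield np.delete(idx, i), np.array([i])
        else:
            if self.k > n:
                raise ConfigurationError(f"fold count {self.k} exceeds n={n}")
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(n)
            for part in np.array_split(perm, self.k):
                test = np.sort(part)
                train = np.sort(np.setdiff1d(perm, part))
                yield train, test

    def label(self) -> str:
        return "leave_one_out" if self.kind == "loo" else f"k_fold({self.k})"


LOO = CVScheme("loo")


@dataclass
class CVTrace:
    """RMSECV per candidate model order or hyperparameter-grid point."""

    candidates: list
    rmsecv: np.ndarray
    selected: object
    cv_scheme: str

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"candidate": [str(c) for c in self.candidates],
                      "rmsecv": self.rmsecv}).to_csv(path, index=False)


@dataclass
class FittedModel:
    """A fitted calibration model, self-contained for prediction.

    Linear methods (MLR/PCR/PLS) store band-space coefficients plus the
    centering statistics; PLS additionally keeps the NIPALS internals
    (unit-norm loading weights W, scores T, x-loadings P, y-loadings q)
    needed for VIP scores and loading-weight profiles.  SVM stores the
    support vectors, dual coefficients and kernel parameters together with
    the standardization statistics.
    """

    method: str
    n_bands: int
    coef: np.ndarray | None = None
    intercept: float = 0.0
    x_mean: np.ndarray | None = None
    y_mean: float | None = None
    selected_order: int | None = None
    hyperparameters: dict = field(default_factory=dict)
    loading_weights: np.ndarray | None = None     # p x A, unit-norm columns
    x_scores: np.ndarray | None = None            # n x A
    x_loadings: np.ndarray | None = None          # p x A
    y_loadings: np.ndarray | None = None          # (A,)
    x_scale: np.ndarray | None = None             # SVM standardization SD
    support_vectors: np.ndarray | None = None     # m x p (standardized)
    dual_coef: np.ndarray | None = None           # (m,)

    # -- prediction --------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_bands:
            raise ShapeError(
                f"model was trained on {self.n_bands} bands, got {X.shape[1]}"
            )
        if self.method == "SVM":
            Z = (X - self.x_mean) / self.x_scale
            g = self.hyperparameters["g"]
            sq = (
                (Z**2).sum(axis=1)[:, None]
                + (self.support_vectors**2).sum(axis=1)[None, :]
                - 2.0 * Z @ self.support_vectors.T
            )
            return np.exp(-g * np.maximum(sq, 0.0)) @ self.dual_coef + self.intercept
        return X @ self.coef + self.intercept

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return {"__array__": v.tolist()}
            return v

        payload = {
            "method": self.method,
            "n_bands": self.n_bands,
            "coef": enc(self.coef),
            "intercept": self.intercept,
            "x_mean": enc(self.x_mean),
            "y_mean": self.y_mean,
            "selected_order": self.selected_order,
            "hyperparameters": self.hyperparameters,
            "loading_weights": enc(self.loading_weights),
            "x_scores": enc(self.x_scores),
            "x_loadings": enc(self.x_loadings),
            "y_loadings": enc(self.y_loadings),
            "x_scale": enc(self.x_scale),
            "support_vectors": enc(self.support_vectors),
            "dual_coef": enc(self.dual_coef),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text(encoding="utf-8") if isinstance(
            source, Path
        ) or (isinstance(source, str) and not source.lstrip().startswith("{")) else source
        payload = json.loads(text)

        def dec(v):
            if isinstance(v, dict) and "__array__" in v:
                return np.asarray(v["__array__"], dtype=float)
            return v

        return cls(**{k: dec(v) for k, v in payload.items()})


# -- helpers ---------------------------------------------------------------

def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise SizeError("empty predictor matrix")
    if X.shape[0] != y.size:
        raise SizeError(f"X has {X.shape[0]} rows but y has {y.size}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise SizeError("X and y must be finite")
    return X, y


def _rmse(errors: list[np.ndarray]) -> float:
    e = np.concatenate([np.atleast_1d(v) for v in errors])
    return float(np.sqrt(np.mean(e**2)))


def _select_minimum(values: np.ndarray) -> int:
    """First index attaining the minimum (parsimony tie-break)."""
    return int(np.argmin(values))


# -- MLR -------------------------------------------------------------------

def fit_mlr(X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Least squares with intercept; minimum-norm solution when X'X is singular."""
    X, y = _validate_xy(X, y)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    coef, *_ = np.linalg.lstsq(X - x_mean, y - y_mean, rcond=None)
    return FittedModel(
        method="MLR",
        n_bands=X.shape[1],
        coef=coef,
        intercept=y_mean - float(x_mean @ coef),
        x_mean=x_mean,
        y_mean=y_mean,
    )


# -- PCR -------------------------------------------------------------------

def _pcr_path(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k_max: int
) -> np.ndarray:
    """Test predictions for k = 1..k_max components; shape (n_test, k_max)."""
    mu = X_train.mean(axis=0)
    ym = y_train.mean()
    U, S, Vt = np.linalg.svd(X_train - mu, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    r = min(k_max, rank)
    if r == 0:
        return np.full((X_test.shape[0], k_max), ym)
    # regression on orthogonal training scores T = U*S: gamma = U'yc / S,
    # so the band-space coefficient per component is V_j * gamma_j
    gamma = (U[:, :r].T @ (y_train - ym)) / S[:r]
    T_test = (X_test - mu) @ Vt[:r].T
    cum = ym + np.cumsum(T_test * gamma, axis=1)
    if r < k_max:
        cum = np.hstack([cum, np.repeat(cum[:, -1:], k_max - r, axis=1)])
    return cum


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    cv_scheme: CVScheme = LOO,
    n_components: int | None = None,
) -> tuple[FittedModel, CVTrace]:
    """PCR with the component count chosen at minimum RMSECV.

    Pass ``n_components`` to skip cross-validation and fit a fixed order.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if max_components < 1:
        raise ConfigurationError("max_components must be >= 1")
    if n_components is not None:
        k_sel = min(n_components, n - 1, p)
        rmsecv = np.array([np.nan])
        candidates: list = [k_sel]
    else:
        k_max = min(max_components, n - 1, p)
        errs: list[list[np.ndarray]] = [[] for _ in range(k_max)]
        for train, test in cv_scheme.folds(n):
            preds = _pcr_path(X[train], y[train], X[test], k_max)
            for k in range(k_max):
                errs[k].append(preds[:, k] - y[test])
        rmsecv = np.array([_rmse(e) for e in errs])
        k_sel = _select_minimum(rmsecv) + 1
        candidates = list(range(1, k_max + 1))

    mu = X.mean(axis=0)
    ym = float(y.mean())
    U, S, Vt = np.linalg.svd(X - mu, full_matrices=False)
    gamma = (U[:, :k_sel].T @ (y - ym)) / S[:k_sel]
    beta = Vt[:k_sel].T @ gamma
    model = FittedModel(
        method="PCR",
        n_bands=p,
        coef=beta,
        intercept=ym - float(mu @ beta),
        x_mean=mu,
        y_mean=ym,
        selected_order=k_sel,
    )
    trace = CVTrace(
        candidates=candidates,
        rmsecv=rmsecv,
        selected=k_sel,
        cv_scheme=cv_scheme.label() if n_components is None else "fixed",
    )
    return model, trace


# -- PLS (NIPALS, single response) ----------------------------------------

def _nipals(
    Xc: np.ndarray, yc: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract up to ``n_components`` PLS1 components from centered data.

    Returns (W, P, q, T): unit-norm weights, x-loadings, y-loadings, scores.
    Stops early if the residual covariance or score norm vanishes.
    """
    n, p = Xc.shape
    Xd = Xc.copy()
    scale = max(float(np.abs(Xc).max()), 1e-300)
    W, P, Q, T = [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale * max(np.abs(yc).max(), 1.0):
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            break
        p_load = Xd.T @ t / tt
        q_load = float(yc @ t / tt)
        Xd -= np.outer(t, p_load)
        W.append(w)
        P.append(p_load)
        Q.append(q_load)
        T.append(t)
    if not W:
        raise DegenerateDataError("no PLS component could be extracted")
    return (
        np.column_stack(W),
        np.column_stack(P),
        np.asarray(Q),
        np.column_stack(T),
    )


def _pls_path(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, a_max: int
) -> np.ndarray:
    """Test predictions for 1..a_max latent variables; shape (n_test, a_max)."""
    mu = X_train.mean(axis=0)
    ym = y_train.mean()
    try:
        W, P, q, _ = _nipals(X_train - mu, y_train - ym, a_max)
    except DegenerateDataError:
        return np.full((X_test.shape[0], a_max), ym)
    a_got = W.shape[1]
    Xd = X_test - mu
    preds = np.empty((X_test.shape[0], a_max))
    acc = np.full(X_test.shape[0], float(ym))
    for a in range(a_got):
        t = Xd @ W[:, a]
        acc = acc + q[a] * t
        Xd = Xd - np.outer(t, P[:, a])
        preds[:, a] = acc
    for a in range(a_got, a_max):
        preds[:, a] = acc
    return preds


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 20,
    cv_scheme: CVScheme = LOO,
    n_lv: int | None = None,
) -> tuple[FittedModel, CVTrace]:
    """NIPALS PLS1 with the latent-variable count chosen at minimum RMSECV.

    Pass ``n_lv`` to skip cross-validation and fit a fixed order.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if max_lv < 1:
        raise ConfigurationError("max_lv must be >= 1")
    if np.ptp(y) == 0:
        raise DegenerateDataError("y has zero variance; PLS undefined")
    if n_lv is not None:
        a_sel = min(n_lv, n - 1, p)
        rmsecv = np.array([np.nan])
        candidates: list = [a_sel]
    else:
        a_max = min(max_lv, n - 1, p)
        errs: list[list[np.ndarray]] = [[] for _ in range(a_max)]
        for train, test in cv_scheme.folds(n):
            preds = _pls_path(X[train], y[train], X[test], a_max)
            for a in range(a_max):
                errs[a].append(preds[:, a] - y[test])
        rmsecv = np.array([_rmse(e) for e in errs])
        a_sel = _select_minimum(rmsecv) + 1
        candidates = list(range(1, a_max + 1))

    mu = X.mean(axis=0)
    ym = float(y.mean())
    W, P, q, T = _nipals(X - mu, y - ym, a_sel)
    a_sel = W.shape[1]  # may shrink on rank-deficient data
    beta = W @ np.linalg.solve(P.T @ W, q)
    model = FittedModel(
        method="PLS",
        n_bands=p,
        coef=beta,
        intercept=ym - float(mu @ beta),
        x_mean=mu,
        y_mean=ym,
        selected_order=a_sel,
        loading_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
    )
    trace = CVTrace(
        candidates=candidates,
        rmsecv=rmsecv,
        selected=a_sel,
        cv_scheme=cv_scheme.label() if n_lv is None else "fixed",
    )
    return model, trace


# -- epsilon-SVR with RBF kernel ------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_svr_rbf(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict[str, Sequence[float]] | None = None,
    cv_scheme: CVScheme = CVScheme("kfold", k=10, seed=0),
) -> tuple[FittedModel, CVTrace]:
    """epsilon-SVR, kernel exp(-g||u-v||^2), grid-searched by RMSECV.

    Predictors are z-score standardized internally (statistics from the
    training split of each fold during CV, from the full data for the
    final fit).
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    grid = dict(DEFAULT_SVR_GRID) if grid is None else dict(grid)
    for key in ("c", "g", "epsilon"):
        if key not in grid or len(grid[key]) == 0:
            raise ConfigurationError(f"SVR grid is missing non-empty {key!r}")
    if any(v <= 0 for v in grid["c"]) or any(v <= 0 for v in grid["g"]):
        raise ConfigurationError("c and g must be positive")

    folds = list(cv_scheme.folds(n))
    combos = [
        (float(c), float(g), float(eps))
        for c in grid["c"]
        for g in grid["g"]
        for eps in grid["epsilon"]
    ]
    rmsecv = np.empty(len(combos))
    fold_data = []
    for train, test in folds:
        Z_train, mu, sd = _standardize(X[train])
        Z_test = (X[test] - mu) / sd
        fold_data.append((Z_train, y[train], Z_test, y[test]))
    for i, (c, g, eps) in enumerate(combos):
        errs = []
        for Z_train, y_train, Z_test, y_test in fold_data:
            svr = SVR(kernel="rbf", C=c, gamma=g, epsilon=eps)
            svr.fit(Z_train, y_train)
            errs.append(svr.predict(Z_test) - y_test)
        rmsecv[i] = _rmse(errs)
    best = _select_minimum(rmsecv)
    c, g, eps = combos[best]

    Z, mu, sd = _standardize(X)
    svr = SVR(kernel="rbf", C=c, gamma=g, epsilon=eps)
    svr.fit(Z, y)
    model = FittedModel(
        method="SVM",
        n_bands=p,
        intercept=float(svr.intercept_[0]),
        x_mean=mu,
        x_scale=sd,
        y_mean=float(y.mean()),
        hyperparameters={"c": c, "g": g, "epsilon": eps},
        support_vectors=Z[svr.support_],
        dual_coef=svr.dual_coef_.ravel(),
    )
    trace = CVTrace(
        candidates=combos,
        rmsecv=rmsecv,
        selected=(c, g, eps),
        cv_scheme=cv_scheme.label(),
    )
    return model, trace


# -- generic facade --------------------------------------------------------

def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Apply a fitted model to new spectra (same band count as training)."""
    return model.predict(X)


def rmsecv(
    fit_fn: Callable[[np.ndarray, np.ndarray], FittedModel],
    X: np.ndarray,
    y: np.ndarray,
    cv_scheme: CVScheme = LOO,
) -> float:
    """Root mean square error of cross-validation for an arbitrary fitter.

    ``fit_fn(X_train, y_train)`` must return an object with ``predict``.
    """
    X, y = _validate_xy(X, y)
    errs = []
    for train, test in cv_scheme.folds(X.shape[0]):
        model = fit_fn(X[train], y[train])
        errs.append(np.asarray(model.predict(X[test])) - y[test])
    return _rmse(errs)
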