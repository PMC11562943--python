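"""Per-instrument LASSO prognostic models of RCSI.

The model is a *linear probability model*: ordinary least squares on the
0/1 RCSI outcome with an l1 penalty,

    minimise  (1/2n) * sum_i (y_i - b0 - x_i' beta)^2  +  lambda * ||beta||_1,

fitted on predictors standardised to unit variance (the intercept is
unpenalised) and reported back on the original feature scale.  The
fitted value ``b0 + x'beta`` is interpreted as an RCSI probability
score; it is returned unclipped because the linear model can leave
[0, 1], with clipping available for presentation.

The penalty ``lambda`` is chosen over a log-spaced grid (default 50
points between 1e-4 and 1e-1) by the .632 bootstrap estimate of
prediction error:

    err632(lambda) = 0.368 * apparent(lambda) + 0.632 * oob(lambda)

where *apparent* is the mean squared error of the full-data fit on the
full data and *oob* averages, over B bootstrap refits, the MSE on each
refit's out-of-bag clients.  Ties in the minimiser break toward the
larger lambda (the sparser model).

Coordinate-descent fitting is delegated to scikit-learn
(:func:`sklearn.linear_model.lasso_path`); the unpenalised case falls
back to a least-squares solve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

__all__ = [
    "LambdaGrid",
    "FittedLassoModel",
    "Dot632Point",
    "Dot632Curve",
    "fit_lasso",
    "dot632_error",
    "select_lambda",
    "predict_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LambdaGrid:
    """Logarithmically spaced penalty grid."""

    lower: float = 1e-4
    upper: float = 1e-1
    n_points: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("grid requires 0 < lower < upper")
        if self.n_points < 2:
            raise ValueError("grid requires n_points >= 2")

    def values(self) -> np.ndarray:
        """Grid values in increasing order."""
        return np.geomspace(self.lower, self.upper, self.n_points)


@dataclass
class FittedLassoModel:
    """Intercept + sparse coefficient map on the original feature scale."""

    instrument: str
    intercept: float
    coefficients: dict[str, float]
    lambda_selected: float
    meta: dict = field(default_factory=dict)

    @property
    def nonzero_features(self) -> list[str]:
        return [name for name, w in self.coefficients.items() if w != 0.0]

    def to_json(self, path) -> None:
        doc = {
            "instrument": self.instrument,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda_selected": self.lambda_selected,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FittedLassoModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(instrument=doc["instrument"], intercept=doc["intercept"],
                   coefficients=doc["coefficients"],
                   lambda_selected=doc["lambda_selected"], meta=doc.get("meta", {}))


@dataclass(frozen=True)
class Dot632Point:
    apparent_error: float
    oob_error: float

    @property
    def err632(self) -> float:
        return 0.368 * self.apparent_error + 0.632 * self.oob_error


@dataclass
class Dot632Curve:
    """Per-lambda .632 bootstrap error profile."""

    lambdas: np.ndarray
    apparent_error: np.ndarray
    oob_error: np.ndarray
    B: int

    @property
    def err632(self) -> np.ndarray:
        return 0.368 * self.apparent_error + 0.632 * self.oob_error

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas,
            "apparent_error": self.apparent_error,
            "oob_error": self.oob_error,
            "err632": self.err632,
        })


# ---------------------------------------------------------------------------
# Core fitting on standardised predictors


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _path_coefs(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Standardised-scale coefficients at each lambda (ascending order).

    Returns (coefs[p, k], mu, sd, ybar); predictions on new data ``Z`` are
    ``ybar + ((Z - mu)/sd) @ coefs``.
    """
    Xs, mu, sd = _standardize(X)
    yc = y - y.mean()
    order = np.argsort(lambdas)[::-1]  # lasso_path wants decreasing alphas
    if np.any(lambdas <= 0):
        coefs = np.empty((X.shape[1], len(lambdas)))
        for k, lam in enumerate(lambdas):
            coefs[:, k] = _single_fit(Xs, yc, float(lam))
    else:
        _, path, _ = lasso_path(Xs, yc, alphas=lambdas[order], tol=1e-7, max_iter=50_000)
        coefs = np.empty_like(path)
        coefs[:, order] = path
    return coefs, mu, sd, float(y.mean())


def _single_fit(Xs: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return beta
    _, path, _ = lasso_path(Xs, yc, alphas=[lam], tol=1e-7, max_iter=50_000)
    return path[:, 0]


def fit_lasso(X, y, lam: float, instrument: str = "",
              family: str = "linear") -> FittedLassoModel:
    """Fit the penalised probability model at a single lambda.

    ``X`` may be a DataFrame (named features) or array.  Predictors are
    standardised internally; coefficients come back on the original
    scale.  An all-constant design yields the intercept-only model
    ``mean(y)``.

    ``family="linear"`` (default) is the linear probability model used
    throughout the pipeline; ``family="logistic"`` fits an l1-penalised
    logistic regression with an equivalent per-observation penalty, as a
    sensitivity-analysis alternative (scores then pass through the
    logistic link in :func:`predict_score`).
    """
    Xa, names = _as_matrix(X)
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError(f"X has {Xa.shape[0]} rows but y has {ya.shape[0]}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xs, mu, sd = _standardize(Xa)
    if family == "linear":
        beta_s = _single_fit(Xs, ya - ya.mean(), lam)
        beta = beta_s / sd
        intercept = float(ya.mean() - beta @ mu)
    elif family == "logistic":
        from sklearn.linear_model import LogisticRegression

        if lam == 0.0:
            clf = LogisticRegression(C=np.inf, max_iter=5000)
        else:
            # sklearn minimises ||b||_1 + C * sum(logloss); our lambda is a
            # per-observation penalty, hence C = 1 / (n * lambda)
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                     C=1.0 / (Xa.shape[0] * lam), max_iter=5000)
        clf.fit(Xs, ya.astype(int))
        beta = clf.coef_[0] / sd
        intercept = float(clf.intercept_[0] - beta @ mu)
    else:
        raise ValueError(f"unknown family {family!r}")
    coefficients = {name: float(b) for name, b in zip(names, beta)}
    model = FittedLassoModel(instrument=instrument, intercept=intercept,
                             coefficients=coefficients, lambda_selected=lam)
    if family != "linear":
        model.meta["family"] = family
    return model


def predict_score(model: FittedLassoModel, x, clip: bool = False) -> np.ndarray:
    """RCSI probability scores ``intercept + x' beta``.

    Unclipped by default (a linear probability model can leave [0, 1]);
    pass ``clip=True`` for a [0, 1] presentation view.  ``x`` may be a
    DataFrame, a feature dict, or an array ordered like the model's
    coefficient map.  Missing named features raise an error listing them.
    """
    names = list(model.coefficients)
    beta = np.asarray([model.coefficients[n] for n in names])
    if isinstance(x, pd.DataFrame):
        missing = [n for n in names if n not in x.columns]
        if missing:
            raise ValueError(f"feature(s) missing from input: {missing}")
        vals = x[names].to_numpy(dtype=float)
    elif isinstance(x, dict):
        missing = [n for n in names if n not in x]
        if missing:
            raise ValueError(f"feature(s) missing from input: {missing}")
        vals = np.asarray([[x[n] for n in names]], dtype=float)
    else:
        vals = np.atleast_2d(np.asarray(x, dtype=float))
        if vals.shape[1] != len(names):
            raise ValueError(f"expected {len(names)} features, got {vals.shape[1]}")
    scores = model.intercept + vals @ beta
    if model.meta.get("family") == "logistic":
        scores = 1.0 / (1.0 + np.exp(-scores))
    if clip:
        scores = np.clip(scores, 0.0, 1.0)
    return scores


# ---------------------------------------------------------------------------
# .632 bootstrap


def _bootstrap_index_sets(n: int, B: int, rng: np.random.Generator) -> list[np.ndarray]:
    """B with-replacement index draws, each guaranteed a non-empty
    out-of-bag set (degenerate draws are logged and redrawn)."""
    sets = []
    while len(sets) < B:
        idx = rng.integers(0, n, n)
        if np.unique(idx).size == n:
            logger.info("bootstrap draw covered every client; redrawn")
            continue
        sets.append(idx)
    return sets


def _errors_by_lambda(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                      index_sets: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    coefs, mu, sd, ybar = _path_coefs(X, y, lambdas)
    fitted = ybar + ((X - mu) / sd) @ coefs
    apparent = ((y[:, None] - fitted) ** 2).mean(axis=0)

    oob_sum = np.zeros(len(lambdas))
    for idx in index_sets:
        oob = np.setdiff1d(np.arange(n), idx)
        bc, bmu, bsd, bybar = _path_coefs(X[idx], y[idx], lambdas)
        pred = bybar + ((X[oob] - bmu) / bsd) @ bc
        oob_sum += ((y[oob, None] - pred) ** 2).mean(axis=0)
    return apparent, oob_sum / len(index_sets)


def dot632_error(X, y, lam: float, B: int = 1000, seed: int = 0) -> Dot632Point:
    """The .632 bootstrap error estimate at a single lambda.

    Deterministic under ``seed``; the bootstrap draws do not depend on
    lambda, so per-lambda calls with one seed are mutually consistent
    (and consistent with :func:`select_lambda`).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    Xa, _ = _as_matrix(X)
    ya = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    index_sets = _bootstrap_index_sets(Xa.shape[0], B, rng)
    apparent, oob = _errors_by_lambda(Xa, ya, np.asarray([lam], dtype=float), index_sets)
    return Dot632Point(apparent_error=float(apparent[0]), oob_error=float(oob[0]))


def select_lambda(X, y, grid: LambdaGrid | Sequence[float] = LambdaGrid(), B: int = 1000,
                  seed: int = 0) -> tuple[float, Dot632Curve]:
    """Minimise err632 over the grid; ties break toward the larger lambda.

    ``grid`` may be a :class:`LambdaGrid` or an explicit sequence of
    penalty values (which may be a single value).
    """
    Xa, _ = _as_matrix(X)
    ya = np.asarray(y, dtype=float)
    lambdas = grid.values() if isinstance(grid, LambdaGrid) else np.sort(np.asarray(grid, dtype=float))
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    rng = np.random.default_rng(seed)
    index_sets = _bootstrap_index_sets(Xa.shape[0], B, rng)
    apparent, oob = _errors_by_lambda(Xa, ya, lambdas, index_sets)
    curve = Dot632Curve(lambdas=lambdas, apparent_error=apparent, oob_error=oob, B=B)
    err = curve.err632
    best = np.flatnonzero(err == err.min()).max()  # larger lambda wins ties
    return float(lambdas[best]), curve
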