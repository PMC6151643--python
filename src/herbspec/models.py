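"""Regression models for analyte content from NIR spectra.

Organised in the style of statsmodels: a model class is constructed
from data (``PLS(y, X, ...)`` or ``Model.from_dataframe(...)``), its
``fit()`` returns a results object carrying the estimates, and
evaluation utilities (:func:`loocv`, :func:`evaluate`, the ``tune_*``
grid searches) operate on light-weight model *specs* so they can refit
on resampled data.

Three model families are provided:

* :class:`PLS` — partial least squares (NIPALS, mean-centering only),
  the linear workhorse of reflectance chemometrics;
* :class:`LSSVM` — least-squares support vector machine with an RBF
  kernel, whose dual problem is a single linear system;
* :class:`ELM` — extreme learning machine, a single-hidden-layer
  network with random input weights and least-squares output weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .axis import SpectralAxis
from .exceptions import DegenerateResponseError, HerbspecError

__all__ = [
    "SampleTable", "SplitTable", "split",
    "PLS", "LSSVM", "ELM",
    "PLSSpec", "LSSVMSpec", "ELMSpec", "spec_for",
    "loocv", "tune_pls", "tune_lssvm", "tune_elm",
    "EvaluationReport", "evaluate",
]


# --------------------------------------------------------------------------
# data containers and splitting
# --------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample spectra matrix X with reference contents y."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    axis: SpectralAxis | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise HerbspecError("X rows and y must align")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise HerbspecError("missing values are not allowed")
        if self.ids is None:
            self.ids = np.arange(self.y.size)
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.y.size

    def take(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(self.X[idx], self.y[idx], self.ids[idx], self.axis)


@dataclass
class SplitTable:
    """Disjoint calibration/prediction division of a sample table."""

    calibration: SampleTable
    prediction: SampleTable
    seed: int

    def __post_init__(self) -> None:
        cal, pred = self.calibration, self.prediction
        if set(map(str, cal.ids)) & set(map(str, pred.ids)):
            raise HerbspecError("calibration and prediction ids overlap")
        if pred.n and (pred.y.min() < cal.y.min() - 1e-12
                       or pred.y.max() > cal.y.max() + 1e-12):
            raise HerbspecError(
                "prediction y-range must be covered by the calibration set"
            )


def split(table: SampleTable, ratio: float = 3.0, seed: int = 0) -> SplitTable:
    """Random calibration/prediction split at calibration:prediction ratio.

    The prediction set gets ``round(n / (1 + ratio))`` samples.  After
    the random draw the assignment is repaired so the samples attaining
    the minimum and maximum of y sit in the calibration set (the
    prediction range must be covered by calibration).
    """
    n = table.n
    if n < 4:
        raise HerbspecError("need at least 4 samples to split")
    n_pred = int(round(n / (1.0 + ratio)))
    n_pred = max(1, min(n_pred, n - 2))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    pred_idx = list(perm[:n_pred])
    cal_idx = list(perm[n_pred:])
    for extreme in (int(np.argmin(table.y)), int(np.argmax(table.y))):
        if extreme in pred_idx:
            # swap with a random calibration sample that is not extreme
            candidates = [i for i in cal_idx
                          if i != np.argmin(table.y) and i != np.argmax(table.y)]
            swap = candidates[int(rng.integers(len(candidates)))]
            pred_idx[pred_idx.index(extreme)] = swap
            cal_idx[cal_idx.index(swap)] = extreme
    cal_idx, pred_idx = np.sort(cal_idx), np.sort(pred_idx)
    return SplitTable(table.take(cal_idx), table.take(pred_idx), seed)


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

class RegressionResults:
    """Fitted-model results: estimates, fit diagnostics, prediction."""

    def __init__(self, model, fittedvalues: np.ndarray):
        self.model = model
        self.fittedvalues = np.asarray(fittedvalues, dtype=float)
        resid = model.y - self.fittedvalues
        self.resid = resid
        self.rmsec = float(np.sqrt(np.mean(resid ** 2)))
        self.r_c = pearson(model.y, self.fittedvalues)

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} regression results",
            "=" * 44,
            f"n samples            {self.model.y.size:>10d}",
            f"n bands              {self.model.X.shape[1]:>10d}",
        ]
        for name, value in self.model._param_items():
            lines.append(f"{name:<20s} {value:>10}")
        lines += [
            f"r_c                  {self.r_c:>10.4f}",
            f"RMSEC (% w/w)        {self.rmsec:>10.5f}",
        ]
        return "\n".join(lines)


class _AffineResults(RegressionResults):
    """Results of a model whose prediction is affine: y = X b + b0."""

    def __init__(self, model, coef: np.ndarray, intercept: float):
        self.coef = np.asarray(coef, dtype=float).ravel()
        self.intercept = float(intercept)
        super().__init__(model, self._affine(model.X))

    def _affine(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            return np.empty(0)
        if X.shape[1] != self.coef.size:
            raise HerbspecError(
                f"model expects {self.coef.size} bands, got {X.shape[1]}"
            )
        return self._affine(X)


# --------------------------------------------------------------------------
# model classes
# --------------------------------------------------------------------------

class SpectralModel:
    """Base class: holds (y, X) and common constructors."""

    def __init__(self, y, X):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise HerbspecError("X rows and y must align")

    @classmethod
    def from_table(cls, table: SampleTable, **kwargs):
        return cls(table.y, table.X, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       bands: Sequence[str] | None = None, **kwargs):
        """Construct from a tidy DataFrame: one response column, the
        remaining (or listed) columns as band reflectances."""
        if bands is None:
            bands = [c for c in df.columns if c != response]
        return cls(df[response].to_numpy(), df[list(bands)].to_numpy(),
                   **kwargs)

    def _param_items(self):
        return []


class PLS(SpectralModel):
    """Partial least squares regression (NIPALS, mean-centered).

    ``n_components`` is the latent-variable (LV) count.  At full rank
    the fit coincides with ordinary least squares.
    """

    def __init__(self, y, X, n_components: int = 2):
        super().__init__(y, X)
        if np.ptp(self.y) == 0:
            raise DegenerateResponseError("y is constant")
        cap = min(self.y.size - 1, self.X.shape[1])
        if not (1 <= n_components <= cap):
            raise HerbspecError(
                f"n_components must be in [1, {cap}], got {n_components}"
            )
        self.n_components = int(n_components)

    def _param_items(self):
        return [("latent variables", self.n_components)]

    def fit(self) -> "PLSResults":
        from sklearn.cross_decomposition import PLSRegression

        pls = PLSRegression(n_components=self.n_components, scale=False)
        with np.errstate(all="ignore"):
            pls.fit(self.X, self.y)
        coef = pls.coef_.ravel()
        # fold the centering into the intercept so prediction is affine
        intercept = float(self.y.mean() - self.X.mean(axis=0) @ coef)
        return PLSResults(self, coef, intercept)


class PLSResults(_AffineResults):
    pass


class LSSVM(SpectralModel):
    """Least-squares SVM regression with a radial-basis-function kernel.

    The dual problem is the linear system

        [ 0   1^T            ] [b]   [0]
        [ 1   K + I / gamma  ] [a] = [y]

    with K_ij = exp(-||x_i - x_j||^2 / sigma2); prediction is
    ``sum_i a_i K(x, x_i) + b``.
    """

    def __init__(self, y, X, gamma: float = 1e4, sigma2: float = 1e4):
        super().__init__(y, X)
        if gamma <= 0 or sigma2 <= 0:
            raise HerbspecError("gamma and sigma2 must be positive")
        self.gamma = float(gamma)
        self.sigma2 = float(sigma2)

    def _param_items(self):
        return [("gamma", f"{self.gamma:.3g}"),
                ("sigma2", f"{self.sigma2:.3g}")]

    @staticmethod
    def _kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
        d2 = (
            np.sum(A ** 2, axis=1)[:, None]
            + np.sum(B ** 2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-np.maximum(d2, 0.0) / sigma2)

    def build_system(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.y.size
        K = self._kernel(self.X, self.X, self.sigma2)
        A = np.empty((n + 1, n + 1))
        A[0, 0] = 0.0
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.concatenate([[0.0], self.y])
        return A, rhs

    def fit(self) -> "LSSVMResults":
        A, rhs = self.build_system()
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise HerbspecError(f"singular LS-SVM dual system: {err}")
        residual = float(np.max(np.abs(A @ sol - rhs)))
        if residual > 1e-6:
            raise HerbspecError(
                f"LS-SVM dual solve residual {residual:.2e} too large"
            )
        return LSSVMResults(self, b=float(sol[0]), alpha=sol[1:],
                            dual_residual=residual)


class LSSVMResults(RegressionResults):
    def __init__(self, model: LSSVM, b: float, alpha: np.ndarray,
                 dual_residual: float):
        self.model = model
        self.b = b
        self.alpha = np.asarray(alpha, dtype=float)
        self.dual_residual = dual_residual
        super().__init__(model, self._raw_predict(model.X))

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        K = LSSVM._kernel(np.atleast_2d(X), self.model.X, self.model.sigma2)
        return K @ self.alpha + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            return np.empty(0)
        if X.shape[1] != self.model.X.shape[1]:
            raise HerbspecError("band count mismatch")
        return self._raw_predict(X)


class ELM(SpectralModel):
    """Extreme learning machine regression.

    Inputs are rescaled to [-1, 1] per band (ranges frozen from the
    calibration data; constant bands map to 0).  Input weights and
    biases are drawn uniform(-1, 1) from ``seed`` — node by node, so a
    smaller network's weights are a prefix of a larger one's — and the
    output weights are the minimum-norm least-squares solution.
    """

    def __init__(self, y, X, n_hidden: int = 20, seed: int = 0,
                 activation: str = "sigmoid"):
        super().__init__(y, X)
        if n_hidden < 1:
            raise HerbspecError("n_hidden must be >= 1")
        if activation not in ("sigmoid", "tanh"):
            raise HerbspecError(f"unknown activation {activation!r}")
        self.n_hidden = int(n_hidden)
        self.seed = int(seed)
        self.activation = activation

    def _param_items(self):
        return [("hidden nodes", self.n_hidden), ("seed", self.seed)]

    def fit(self) -> "ELMResults":
        lo = self.X.min(axis=0)
        hi = self.X.max(axis=0)
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        Xs = np.where(span > 0, 2.0 * (self.X - lo) / safe - 1.0, 0.0)
        rng = np.random.default_rng(self.seed)
        d = self.X.shape[1]
        # one (weights, bias) row per node keeps smaller nets prefixes
        wb = rng.uniform(-1.0, 1.0, size=(self.n_hidden, d + 1))
        W, b = wb[:, :d], wb[:, d]
        H = _activate(Xs @ W.T + b, self.activation)
        beta, *_ = np.linalg.lstsq(H, self.y, rcond=None)
        return ELMResults(self, W=W, b=b, beta=beta, lo=lo, hi=hi)


def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.tanh(z)


class ELMResults(RegressionResults):
    def __init__(self, model: ELM, W, b, beta, lo, hi):
        self.model = model
        self.W, self.b, self.beta = W, b, beta
        self.lo, self.hi = lo, hi
        super().__init__(model, self._raw_predict(model.X))

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        span = self.hi - self.lo
        safe = np.where(span > 0, span, 1.0)
        Xs = np.where(span > 0, 2.0 * (X - self.lo) / safe - 1.0, 0.0)
        H = _activate(Xs @ self.W.T + self.b, self.model.activation)
        return H @ self.beta

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            return np.empty(0)
        if X.shape[1] != self.model.X.shape[1]:
            raise HerbspecError("band count mismatch")
        return self._raw_predict(X)


# --------------------------------------------------------------------------
# model specs (refittable descriptions) and cross-validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSSpec:
    n_components: int = 2
    kind: str = field(default="pls", init=False)

    def build(self, y, X) -> PLS:
        n_comp = min(self.n_components,
                     np.asarray(y).size - 1, np.atleast_2d(X).shape[1])
        return PLS(y, X, n_components=n_comp)


@dataclass(frozen=True)
class LSSVMSpec:
    gamma: float = 1e4
    sigma2: float = 1e4
    kind: str = field(default="lssvm", init=False)

    def build(self, y, X) -> LSSVM:
        return LSSVM(y, X, gamma=self.gamma, sigma2=self.sigma2)


@dataclass(frozen=True)
class ELMSpec:
    n_hidden: int = 20
    seed: int = 0
    activation: str = "sigmoid"
    kind: str = field(default="elm", init=False)

    def build(self, y, X) -> ELM:
        # same seed in every refit: CV variation reflects the data, not
        # reinitialisation of the random layer
        return ELM(y, X, n_hidden=self.n_hidden, seed=self.seed,
                   activation=self.activation)


ModelSpec = PLSSpec | LSSVMSpec | ELMSpec


def spec_for(kind: str, **hyper) -> ModelSpec:
    """Build a model spec from its family name and hyperparameters."""
    table: dict[str, Callable[..., ModelSpec]] = {
        "pls": PLSSpec, "lssvm": LSSVMSpec, "elm": ELMSpec,
    }
    if kind not in table:
        raise HerbspecError(f"unknown model kind {kind!r}")
    return table[kind](**hyper)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either side has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def loocv(spec: ModelSpec, table: SampleTable) -> tuple[float, float]:
    """Leave-one-out cross-validation: returns (r_cv, RMSECV).

    Each sample is predicted by a model refit on the other n-1; the
    held-out predictions are pooled against the reference contents.
    """
    n = table.n
    if n < 3:
        raise HerbspecError("LOOCV needs at least 3 samples")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            res = spec.build(table.y[keep], table.X[keep]).fit()
        except HerbspecError as err:
            raise HerbspecError(f"LOOCV refit failed at sample {i}: {err}")
        preds[i] = res.predict(table.X[i:i + 1])[0]
    return pearson(table.y, preds), rmse(table.y, preds)


# --------------------------------------------------------------------------
# hyperparameter tuning
# --------------------------------------------------------------------------

def tune_pls(table: SampleTable, max_lv: int = 15) -> tuple[PLSSpec, dict]:
    """Choose the LV count minimising LOOCV RMSECV (ties -> fewer LVs)."""
    cap = min(max_lv, table.n - 2, table.X.shape[1])
    trace = {}
    best, best_rmse = None, np.inf
    for lv in range(1, cap + 1):
        _, r = loocv(PLSSpec(lv), table)
        trace[lv] = r
        if r < best_rmse - 1e-15:
            best, best_rmse = lv, r
    return PLSSpec(best), {"rmsecv": trace}


def _lssvm_fast_loo(table: SampleTable, gamma: float, sigma2: float) -> float:
    """Closed-form LOO RMSE for LS-SVM.

    For the dual system A s = [0; y], the leave-one-out residual of
    sample i is alpha_i / (A^-1)_{i+1,i+1} (Cawley & Talbot identity),
    so the whole grid search needs one factorisation per grid point.
    """
    model = LSSVM(table.y, table.X, gamma=gamma, sigma2=sigma2)
    A, rhs = model.build_system()
    Ainv = np.linalg.inv(A)
    sol = Ainv @ rhs
    alpha = sol[1:]
    diag = np.diag(Ainv)[1:]
    return float(np.sqrt(np.mean((alpha / diag) ** 2)))


def tune_lssvm(
    table: SampleTable,
    gamma_grid: Sequence[float] | None = None,
    sigma2_grid: Sequence[float] | None = None,
) -> tuple[LSSVMSpec, dict]:
    """2-D logarithmic grid search over (gamma, sigma2) by LOO RMSE."""
    if gamma_grid is None:
        gamma_grid = np.logspace(0, 12, 13)
    if sigma2_grid is None:
        sigma2_grid = np.logspace(0, 10, 11)
    best, best_rmse = None, np.inf
    trace = {}
    for g in gamma_grid:
        for s in sigma2_grid:
            r = _lssvm_fast_loo(table, g, s)
            trace[(float(g), float(s))] = r
            if r < best_rmse - 1e-15:
                best, best_rmse = (float(g), float(s)), r
    if best is None:
        raise HerbspecError("all LS-SVM grid points failed")
    return LSSVMSpec(gamma=best[0], sigma2=best[1]), {"rmsecv": trace}


def tune_elm(
    table: SampleTable,
    hidden_grid: Sequence[int] = (5, 10, 15, 20, 25, 30, 35, 40),
    seed: int = 0,
) -> tuple[ELMSpec, dict]:
    """Choose the hidden-node count minimising LOOCV RMSECV (ties ->
    smaller network)."""
    trace = {}
    best, best_rmse = None, np.inf
    for h in hidden_grid:
        _, r = loocv(ELMSpec(n_hidden=h, seed=seed), table)
        trace[h] = r
        if r < best_rmse - 1e-15:
            best, best_rmse = h, r
    if best is None:
        raise HerbspecError("no feasible hidden-node count in grid")
    return ELMSpec(n_hidden=best, seed=seed), {"rmsecv": trace}


# --------------------------------------------------------------------------
# evaluation report
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Calibration / cross-validation / prediction performance of one
    model spec on one split, in the conventional chemometrics layout."""

    model_kind: str
    params: dict
    r_c: float
    rmsec: float
    r_cv: float
    rmsecv: float
    r_p: float
    rmsep: float

    def as_row(self) -> dict:
        return {
            "model": self.model_kind, "params": self.params,
            "r_c": self.r_c, "RMSEC": self.rmsec,
            "r_cv": self.r_cv, "RMSECV": self.rmsecv,
            "r_p": self.r_p, "RMSEP": self.rmsep,
        }

    def summary(self) -> str:
        fmt = lambda v: "   nan" if np.isnan(v) else f"{v:.4f}"
        return (
            f"{self.model_kind.upper():<8s}"
            f" r_c={fmt(self.r_c)} RMSEC={self.rmsec:.5f}"
            f" r_cv={fmt(self.r_cv)} RMSECV={self.rmsecv:.5f}"
            f" r_p={fmt(self.r_p)} RMSEP={self.rmsep:.5f}"
        )


def evaluate(spec: ModelSpec, split_table: SplitTable) -> EvaluationReport:
    """Fit on calibration, LOO-cross-validate, predict the held-out set.

    Pearson r and RMSE are reported for all three stages; zero-variance
    predictions give r = NaN while the RMSE is still computed.
    """
    cal, pred = split_table.calibration, split_table.prediction
    res = spec.build(cal.y, cal.X).fit()
    r_cv, rmsecv = loocv(spec, cal)
    yhat = res.predict(pred.X)
    params = {k: v for k, v in vars(spec).items() if k != "kind"}
    return EvaluationReport(
        model_kind=spec.kind, params=params,
        r_c=res.r_c, rmsec=res.rmsec,
        r_cv=r_cv, rmsecv=rmsecv,
        r_p=pearson(pred.y, yhat), rmsep=rmse(pred.y, yhat),
    )
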