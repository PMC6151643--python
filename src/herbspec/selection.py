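"""Optimal-wavelength selection over the calibration matrix.

Four selectors, all returning a :class:`SelectionResult`:

* :func:`spa` — successive projections algorithm: greedy chains that
  minimise collinearity via orthogonal projections, evaluated by
  multiple-linear-regression leave-one-out RMSE;
* :func:`bw` — weighted regression coefficients: |coefficients| of a
  PLS model on autoscaled spectra;
* :func:`cars` — competitive adaptive reweighted sampling: Monte-Carlo
  PLS runs with an exponentially decreasing survivor schedule and
  adaptive reweighted resampling;
* :func:`random_frog` — reversible-jump subset search yielding
  per-band selection frequencies.

The stochastic selectors take an explicit seed and, to make their
output invariant to the ordering of input samples, canonically sort the
samples before drawing anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .axis import SpectralAxis
from .exceptions import SelectionError

__all__ = [
    "SelectionResult", "CARSConfig", "RFConfig",
    "spa", "bw", "cars", "random_frog", "edf_schedule",
]


@dataclass
class SelectionResult:
    """Selected band indices with per-band scores and provenance."""

    method: str
    selected: np.ndarray            # indices into the (truncated) axis
    scores: np.ndarray              # one score per band of the input matrix
    config: dict = field(default_factory=dict)
    seed: int | None = None
    axis: SpectralAxis | None = None
    rmse: float | None = None       # criterion value of the chosen subset
    trace: np.ndarray | None = None  # per-iteration criterion, if any

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size < 1:
            raise SelectionError("empty selection")
        if np.unique(self.selected).size != self.selected.size:
            raise SelectionError("selected indices must be unique")

    @property
    def selected_nm(self) -> np.ndarray | None:
        if self.axis is None:
            return None
        return self.axis.centers[self.selected]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": self.selected.tolist(),
            "selected_nm": None if self.axis is None
            else [round(float(v), 4) for v in self.selected_nm],
            "scores": np.asarray(self.scores, dtype=float).tolist(),
            "config": self.config,
            "seed": self.seed,
            "rmse": self.rmse,
        }


# --------------------------------------------------------------------------
# shared PLS helpers (internal, seeded 5-fold CV)
# --------------------------------------------------------------------------

def _pls_coef(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Coefficient vector of a mean-centered PLS fit (LV count capped)."""
    from sklearn.cross_decomposition import PLSRegression

    n, p = X.shape
    lv = max(1, min(max_lv, n - 1, p))
    pls = PLSRegression(n_components=lv, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, y)
    return pls.coef_.ravel()


def _pls_fit_predict(X_train, y_train, X_test, max_lv) -> np.ndarray:
    from sklearn.cross_decomposition import PLSRegression

    n, p = X_train.shape
    lv = max(1, min(max_lv, n - 1, p))
    pls = PLSRegression(n_components=lv, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X_train, y_train)
    return pls.predict(X_test).ravel()


def pls_rmsecv(X: np.ndarray, y: np.ndarray, max_lv: int,
               n_folds: int = 5, seed: int = 0) -> float:
    """Seeded k-fold RMSECV of a PLS model restricted to given bands."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, min(n_folds, n))
    preds = np.empty(n)
    for fold in folds:
        keep = np.setdiff1d(np.arange(n), fold)
        preds[fold] = _pls_fit_predict(X[keep], y[keep], X[fold], max_lv)
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample ordering independent of input order (y, then X columns)."""
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (y,)
    return np.lexsort(keys)


# --------------------------------------------------------------------------
# SPA
# --------------------------------------------------------------------------

def _mlr_loo_rmse(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out RMSE of multiple linear regression (hat-matrix
    identity: e_loo = e / (1 - h))."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    # hat diagonal via pseudo-inverse to stay defined when rank-deficient
    Ap = np.linalg.pinv(A)
    h = np.einsum("ij,ji->i", A, Ap)
    denom = np.clip(1.0 - h, 1e-12, None)
    return float(np.sqrt(np.mean((resid / denom) ** 2)))


def _spa_chain(X: np.ndarray, start: int, max_vars: int,
               tol: float = 1e-10) -> list[int]:
    """Projection chain from one starting band.

    Repeatedly projects all columns onto the orthogonal complement of
    the chosen set and picks the largest residual norm (ties -> lowest
    band index).  Stops early when every residual is numerically zero.
    """
    R = X.copy()
    scale = max(np.linalg.norm(X, axis=0).max(), 1.0)
    chain = [start]
    for _ in range(max_vars - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= tol * scale:
            break
        v = v / nv
        R = R - np.outer(v, v @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))  # argmax takes the lowest index on ties
        if norms[best] <= tol * scale:
            break
        chain.append(best)
    return chain


def spa(
    X: np.ndarray,
    y: np.ndarray,
    max_vars: int = 15,
    min_vars: int = 2,
    axis: SpectralAxis | None = None,
) -> SelectionResult:
    """Successive projections algorithm.

    For every possible starting band a projection chain of up to
    ``max_vars`` bands is grown; every chain prefix (of at least
    ``min_vars`` bands) is scored by MLR leave-one-out RMSE and the
    global minimiser returned, in selection order.  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not (1 <= max_vars < min(n, p)):
        raise SelectionError(
            f"max_vars must be in [1, {min(n, p) - 1}], got {max_vars}"
        )
    min_vars = max(1, min(min_vars, max_vars))
    best: tuple[float, int, int] | None = None  # (rmse, k, start)
    best_chain: list[int] | None = None
    for start in range(p):
        chain = _spa_chain(X, start, max_vars)
        for k in range(min_vars, len(chain) + 1):
            r = _mlr_loo_rmse(X[:, chain[:k]], y)
            key = (r, k, start)
            if best is None or key < best:
                best, best_chain = key, chain[:k]
    assert best_chain is not None
    scores = np.zeros(p)
    # score = residual projection norm at the moment of selection
    R = X.copy()
    for j in best_chain:
        scores[j] = np.linalg.norm(R[:, j])
        v = R[:, j]
        nv = np.linalg.norm(v)
        if nv > 0:
            v = v / nv
            R = R - np.outer(v, v @ R)
    return SelectionResult(
        method="spa", selected=np.array(best_chain), scores=scores,
        config={"max_vars": max_vars, "min_vars": min_vars},
        axis=axis, rmse=best[0],
    )


# --------------------------------------------------------------------------
# Bw
# --------------------------------------------------------------------------

def bw(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int = 7,
    top_k: int | None = 13,
    axis: SpectralAxis | None = None,
) -> SelectionResult:
    """Weighted-regression-coefficient selection.

    Every band is autoscaled (zero mean, unit variance) so the PLS
    regression coefficients are comparable across bands; the score is
    |coefficient|.  ``top_k`` bands are kept (``None`` switches to the
    mean + 1 sd threshold rule).  Selected bands are reported in axis
    order.  Zero-variance bands are excluded with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise SelectionError(f"n_lv must be in [1, {min(n - 1, p)}]")
    sd = X.std(axis=0, ddof=0)
    live = sd > 0
    if not live.all():
        warnings.warn(
            f"{int((~live).sum())} zero-variance band(s) excluded from "
            "Bw scoring", stacklevel=2,
        )
    Xs = np.zeros_like(X)
    Xs[:, live] = (X[:, live] - X[:, live].mean(axis=0)) / sd[live]
    coef = _pls_coef(Xs[:, live], y, n_lv)
    scores = np.zeros(p)
    scores[live] = np.abs(coef)
    if top_k is not None:
        k = min(top_k, int(live.sum()))
        # stable argsort on (-score, index): ties -> lowest band index
        order = np.argsort(-scores, kind="stable")[:k]
        selected = np.sort(order)
    else:
        thr = scores[live].mean() + scores[live].std(ddof=0)
        selected = np.flatnonzero(scores >= thr)
        if selected.size == 0:
            selected = np.array([int(np.argmax(scores))])
    return SelectionResult(
        method="bw", selected=selected, scores=scores,
        config={"n_lv": n_lv, "top_k": top_k}, axis=axis,
    )


# --------------------------------------------------------------------------
# CARS
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CARSConfig:
    """Competitive adaptive reweighted sampling settings."""

    n_mc: int = 50              # Monte-Carlo iterations N
    sampling_ratio: float = 0.8  # fraction of calibration samples per run
    max_lv: int = 10
    seed: int = 0
    #: cap on the returned subset: the minimum-RMSECV iteration is taken
    #: among live sets of at most this size (None = unrestricted), so the
    #: default configuration keeps at most 26 bands like the reference
    #: workflow's largest selection
    max_selected: int | None = 26

    def __post_init__(self) -> None:
        if self.n_mc < 2:
            raise SelectionError("n_mc must be >= 2")
        if not (0.5 < self.sampling_ratio < 1.0):
            raise SelectionError("sampling_ratio must be in (0.5, 1)")
        if self.max_lv < 1:
            raise SelectionError("max_lv must be >= 1")


def edf_schedule(p: int, n_mc: int) -> np.ndarray:
    """Exponentially decreasing enforced-survivor counts.

    ``ceil(p * a * exp(-k * i))`` for i = 1..N with the two-point
    calibration a*exp(-k) = 1 and a*exp(-k*N) = 2/p, so the schedule
    starts at p and ends at 2.
    """
    i = np.arange(1, n_mc + 1, dtype=float)
    k = np.log(p / 2.0) / (n_mc - 1)
    a = np.exp(k)
    return np.ceil(p * a * np.exp(-k * i)).astype(int)


def cars(
    X: np.ndarray,
    y: np.ndarray,
    config: CARSConfig = CARSConfig(),
    axis: SpectralAxis | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each iteration fits PLS on a random subset of samples over the live
    bands, keeps the EDF-mandated count of largest-|coefficient| bands,
    resamples them adaptively in proportion to |coefficient|, and
    records the 5-fold RMSECV of the surviving set on all samples.  The
    live set with minimum RMSECV wins (ties -> earliest iteration).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    m = int(round(config.sampling_ratio * n))
    schedule = edf_schedule(p, config.n_mc)
    live = np.arange(p)
    counts = np.zeros(p)
    trace = np.empty(config.n_mc)
    sets: list[np.ndarray] = []
    for it in range(config.n_mc):
        sub = rng.choice(n, size=m, replace=False)
        w = np.abs(_pls_coef(X[np.ix_(sub, live)], y[sub], config.max_lv))
        r_i = min(schedule[it], live.size)
        # enforced survivors: top-|RC| bands, ties -> lowest band index
        keep = np.argsort(-w, kind="stable")[:r_i]
        live, w = live[keep], w[keep]
        # adaptive reweighted sampling: weighted draw with replacement
        if w.sum() > 0:
            drawn = rng.choice(live.size, size=r_i, replace=True,
                               p=w / w.sum())
            new_live = np.unique(live[drawn])
            if new_live.size < 2:
                # top-up guard: replacement sampling collapsed the set
                extra = live[np.argsort(-w, kind="stable")]
                for j in extra:
                    if j not in new_live:
                        new_live = np.sort(np.append(new_live, j))
                    if new_live.size >= 2:
                        break
            live = new_live
        live = np.sort(live)
        counts[live] += 1
        trace[it] = pls_rmsecv(X[:, live], y, config.max_lv,
                               seed=config.seed + 7)
        sets.append(live.copy())
        if live.size < 2:
            raise SelectionError("fewer than 2 live bands mid-schedule")
    sizes = np.array([s.size for s in sets])
    eligible = np.flatnonzero(
        sizes <= (config.max_selected or sizes.max()))
    best_it = int(eligible[np.argmin(trace[eligible])])
    return SelectionResult(
        method="cars", selected=sets[best_it], scores=counts / config.n_mc,
        config={"n_mc": config.n_mc, "sampling_ratio": config.sampling_ratio,
                "max_lv": config.max_lv},
        seed=config.seed, axis=axis, rmse=float(trace[best_it]), trace=trace,
    )


# --------------------------------------------------------------------------
# random frog
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    """Random-frog settings."""

    n_iter: int = 500           # iterations N
    q_init: int = 13            # initial subset size Q
    accept_factor: float = 0.1  # eta: worse-candidate acceptance scale
    jump_sd_factor: float = 0.3  # proposal sd = factor * q_init
    top_k: int = 26
    max_lv: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 10:
            raise SelectionError("n_iter must be >= 10")
        if self.q_init < 1:
            raise SelectionError("q_init must be >= 1")
        if not (0 < self.accept_factor <= 1):
            raise SelectionError("accept_factor must be in (0, 1]")


def random_frog(
    X: np.ndarray,
    y: np.ndarray,
    config: RFConfig = RFConfig(),
    axis: SpectralAxis | None = None,
) -> SelectionResult:
    """Reversible-jump subset search with per-band selection frequencies.

    From a random initial subset, each iteration proposes a resized
    subset (normal jump around the current size; bands added from a
    random pool / removed by |PLS coefficient| ranking), accepting
    improvements always and worsenings with probability
    ``eta * (RMSECV_current / RMSECV_candidate)``.  A band's score is
    the fraction of iterations whose accepted subset contains it; the
    ``top_k`` highest-scoring bands are returned in descending score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    n, p = X.shape
    if config.q_init > p:
        raise SelectionError("q_init exceeds the band count")
    rng = np.random.default_rng(config.seed)
    cv_seed = config.seed + 13

    subset = np.sort(rng.choice(p, size=config.q_init, replace=False))
    current_rmse = pls_rmsecv(X[:, subset], y, config.max_lv, seed=cv_seed)
    counts = np.zeros(p)
    jump_sd = config.jump_sd_factor * config.q_init
    for _ in range(config.n_iter):
        q_star = int(round(rng.normal(subset.size, jump_sd)))
        q_star = max(1, min(p, q_star))
        if q_star <= subset.size:
            w = np.abs(_pls_coef(X[:, subset], y, config.max_lv))
            keep = np.argsort(-w, kind="stable")[:q_star]
            candidate = np.sort(subset[keep])
        else:
            outside = np.setdiff1d(np.arange(p), subset)
            n_add = min(2 * (q_star - subset.size), outside.size)
            pool = np.concatenate([
                subset, rng.choice(outside, size=n_add, replace=False),
            ]) if n_add else subset
            pool = np.sort(pool)
            w = np.abs(_pls_coef(X[:, pool], y, config.max_lv))
            keep = np.argsort(-w, kind="stable")[:min(q_star, pool.size)]
            candidate = np.sort(pool[keep])
        cand_rmse = pls_rmsecv(X[:, candidate], y, config.max_lv,
                               seed=cv_seed)
        if cand_rmse <= current_rmse or (
            rng.random() < config.accept_factor * current_rmse / cand_rmse
        ):
            subset, current_rmse = candidate, cand_rmse
        counts[subset] += 1
    scores = counts / config.n_iter
    k = min(config.top_k, p)
    selected = np.argsort(-scores, kind="stable")[:k]
    return SelectionResult(
        method="rf", selected=selected, scores=scores,
        config={"n_iter": config.n_iter, "q_init": config.q_init,
                "accept_factor": config.accept_factor,
                "top_k": config.top_k, "max_lv": config.max_lv},
        seed=config.seed, axis=axis, rmse=current_rmse,
    )
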