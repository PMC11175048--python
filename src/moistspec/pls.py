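"""Partial least squares regression (PLS1, NIPALS) and repeated double
cross-validation (rdCV) for latent-variable selection.

rdCV evaluates a model in two nested loops: the inner 10-fold CV selects
the number of latent variables (LVs) minimizing the standard error of
prediction (SEP), the outer 4-fold CV estimates prediction error with that
choice, and the whole scheme is repeated (default 100 times) with fresh
random splits.  The final LV count is the mode of all outer-fold selections
(ties to the smaller count); the full selection distribution is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .exceptions import DegenerateInputError

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Mean-centred PLS1 fit (no variance scaling).

    ``W`` are the X-weights, ``P`` the X-loadings and ``q`` the y-loadings,
    one column/entry per latent variable; ``coef`` is the regression vector
    in original X units so that yhat = (X - x_mean) @ coef + y_mean.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # p x a
    P: np.ndarray  # p x a
    q: np.ndarray  # a
    coef: np.ndarray  # p

    def coef_at(self, k: int) -> np.ndarray:
        """Regression vector truncated to the first ``k`` latent variables."""
        if not (1 <= k <= self.n_lv):
            raise ValueError(f"k must lie in [1, {self.n_lv}]")
        R = self.P[:, :k].T @ self.W[:, :k]  # upper triangular (bidiagonal)
        return self.W[:, :k] @ np.linalg.solve(R, self.q[:k])


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """NIPALS PLS1 with mean-centred X and y.

    If the centred data run out of rank before ``n_lv`` components the fit
    stops early and the achieved count is recorded in ``model.n_lv``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, p)}]")
    if np.std(y) == 0:
        raise DegenerateInputError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale0 = float(np.linalg.norm(Xc.T @ yc))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    achieved = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-14 * max(scale0, 1e-300):
            break  # rank exhausted
        w = w / wn
        # for a univariate response NIPALS converges in one pass, but the
        # iteration is kept for robustness
        for _ in range(_NIPALS_MAX_ITER):
            t = Xc @ w
            tt = float(t @ t)
            if tt <= 0:
                break
            w_new = Xc.T @ yc
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new = w_new / nrm
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-28 * max(scale0, 1e-300):
            break
        p_load = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q_a * t
        W[:, a] = w
        P[:, a] = p_load
        q[a] = q_a
        achieved += 1

    if achieved == 0:
        raise DegenerateInputError("no usable latent variable (X^T y is zero)")
    model = PLSModel(
        n_lv=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W[:, :achieved],
        P=P[:, :achieved],
        q=q[:achieved],
        coef=np.zeros(p),
    )
    model.coef = model.coef_at(achieved)
    return model


def predict(model: PLSModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """yhat = (X - x_mean) @ coef + y_mean, optionally truncated to ``k``
    latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.x_mean):
        raise ValueError("X width does not match the model")
    coef = model.coef if k is None else model.coef_at(k)
    return (X - model.x_mean) @ coef + model.y_mean


def sep(residuals: np.ndarray) -> float:
    """Standard error of prediction: sample sd (n-1) of the residuals."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if len(residuals) < 2:
        raise ValueError("need at least 2 residuals")
    return float(np.std(residuals, ddof=1))


@dataclass
class RdcvResult:
    """Outcome of a repeated double cross-validation run."""

    lv_selections: list[int]
    final_lv: int
    sep_by_lv: np.ndarray  # mean inner-loop SEP per candidate LV (1-based index - 1)
    outer_rmse_mean: float
    outer_r2_mean: float
    outer_rmse_per_rep: np.ndarray
    outer_r2_per_rep: np.ndarray
    lv_max: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "lv_selections": [int(v) for v in self.lv_selections],
                    "final_lv": int(self.final_lv),
                    "sep_by_lv": self.sep_by_lv.tolist(),
                    "outer_rmse_mean": float(self.outer_rmse_mean),
                    "outer_r2_mean": float(self.outer_r2_mean),
                    "outer_rmse_per_rep": self.outer_rmse_per_rep.tolist(),
                    "outer_r2_per_rep": self.outer_r2_per_rep.tolist(),
                    "lv_max": int(self.lv_max),
                    "seed": int(self.seed),
                },
                fh,
            )


def _random_folds(rng: np.random.Generator, n: int, k: int) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k) if len(fold)]


def _inner_select_lv(
    X: np.ndarray,
    y: np.ndarray,
    lv_max: int,
    inner_folds: int,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """10-fold (by default) CV on the outer-training part; returns the LV
    minimizing SEP (tie -> smaller) and the SEP curve."""
    n = len(y)
    k = min(inner_folds, n)
    folds = _random_folds(rng, n, k)
    residuals: list[list[float]] = [[] for _ in range(lv_max)]
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        a_fit = min(lv_max, int(mask.sum()) - 1, X.shape[1])
        model = fit_pls(X[mask], y[mask], a_fit)
        for k_lv in range(1, lv_max + 1):
            k_eff = min(k_lv, model.n_lv)
            pred = predict(model, X[fold], k=k_eff)
            residuals[k_lv - 1].extend((y[fold] - pred).tolist())
    sep_curve = np.array([sep(np.asarray(r)) for r in residuals])
    best = int(np.argmin(sep_curve)) + 1  # argmin returns the first = smaller LV
    return best, sep_curve


def rdcv(
    X: np.ndarray,
    y: np.ndarray,
    lv_max: int | None = None,
    outer_folds: int = 4,
    inner_folds: int = 10,
    repetitions: int = 100,
    seed: int = 0,
) -> RdcvResult:
    """Repeated double cross-validation for PLS1.

    Per repetition: a random outer partition; per outer fold, the inner CV
    on the outer-training part picks the LV count with minimum SEP, a model
    with that count predicts the held-out fold.  Outer RMSE and R^2 are
    computed per repetition from the assembled out-of-fold predictions and
    averaged; ``final_lv`` is the mode of all outer-fold selections.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if outer_folds < 2 or (n < outer_folds * 2 and outer_folds != n):
        # outer_folds == n is the leave-one-out limit and is allowed
        raise ValueError("need at least 2 samples per outer fold")
    hard_cap = min(
        20,
        int(np.floor(n * (outer_folds - 1) / outer_folds
                     * (inner_folds - 1) / inner_folds)) - 1,
        p,
    )
    lv_max = hard_cap if lv_max is None else min(lv_max, hard_cap)
    if lv_max < 1:
        raise ValueError("too few samples for even one latent variable")

    rng = np.random.default_rng(seed)
    selections: list[int] = []
    sep_curves: list[np.ndarray] = []
    rmse_per_rep = np.zeros(repetitions)
    r2_per_rep = np.zeros(repetitions)
    ss_tot_all = None
    for rep in range(repetitions):
        folds = _random_folds(rng, n, outer_folds)
        oof = np.full(n, np.nan)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            X_tr, y_tr = X[mask], y[mask]
            best_lv, sep_curve = _inner_select_lv(X_tr, y_tr, lv_max, inner_folds, rng)
            sep_curves.append(sep_curve)
            model = fit_pls(X_tr, y_tr, best_lv)
            oof[fold] = predict(model, X[fold])
            selections.append(best_lv)
        res = y - oof
        rmse_per_rep[rep] = float(np.sqrt(np.mean(res**2)))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2_per_rep[rep] = 1.0 - float(np.sum(res**2)) / ss_tot

    counts = np.bincount(selections, minlength=lv_max + 1)
    final_lv = int(np.argmax(counts))  # argmax -> smallest LV on ties
    return RdcvResult(
        lv_selections=selections,
        final_lv=final_lv,
        sep_by_lv=np.mean(np.vstack(sep_curves), axis=0),
        outer_rmse_mean=float(rmse_per_rep.mean()),
        outer_r2_mean=float(r2_per_rep.mean()),
        outer_rmse_per_rep=rmse_per_rep,
        outer_r2_per_rep=r2_per_rep,
        lv_max=lv_max,
        seed=seed,
    )
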