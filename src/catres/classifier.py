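"""L1-regularized logistic regression.

The classifier minimizes the average logistic loss plus an L1 penalty on
the weight vector (the intercept is not penalized):

.. math::

   \\min_{w, v} \\; \\frac{1}{m} \\sum_{i=1}^m
   \\log\\bigl(1 + e^{-y_i (w^\\top x_i + v)}\\bigr) + \\lambda \\|w\\|_1

with labels :math:`y_i \\in \\{+1, -1\\}`.  The problem is convex; the
solver is FISTA (accelerated proximal gradient with adaptive restart) with
soft-thresholding on the weights only, run to a KKT-residual tolerance so
the returned point is within solver tolerance of the global optimum.  The
solve is fully deterministic.

The module follows the model/results convention: :class:`L1Logreg` is
built from data, its :meth:`~L1Logreg.fit` returns
:class:`L1LogregResults` carrying the fitted :class:`L1LogregModel`,
convergence diagnostics and a weight summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import WindowLayout, WindowedDataset
from .errors import ValidationError

__all__ = [
    "L1LogregModel",
    "TrainConfig",
    "L1Logreg",
    "L1LogregResults",
    "logistic_objective",
    "lambda_max",
    "fit",
    "predict_scores",
]


@dataclass
class L1LogregModel:
    """A fitted sparse logistic model.

    ``threshold`` is the probability cutoff used to turn scores into calls;
    it is chosen by the evaluation module (maximal-F operating point) and
    defaults to 0.5.
    """

    w: np.ndarray
    v: float
    lam: float
    layout: WindowLayout
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (self.layout.dim,):
            raise ValidationError(
                f"weight vector has {self.w.shape[0]} entries, layout "
                f"dimension is {self.layout.dim}"
            )
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.v)):
            raise ValidationError("model parameters must be finite")
        if not self.lam > 0:
            raise ValidationError("lambda must be positive")

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.w))


@dataclass
class TrainConfig:
    """Solver settings.

    ``tolerance`` bounds the maximal KKT (subgradient-optimality) residual
    at the returned point; the seed is reserved (the solver is
    deterministic).
    """

    tolerance: float = 1e-8
    max_iterations: int = 100000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be positive")


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValidationError("labels must be +1 or -1")
    return y.astype(float)


def logistic_objective(w: np.ndarray, v: float, X: np.ndarray,
                       y: np.ndarray, lam: float) -> float:
    """Average logistic loss plus L1 penalty, numerically stable."""
    y = _check_labels(y)
    w = np.asarray(w, dtype=float)
    margins = y * (X @ w + v)
    # log(1 + exp(-t)) = logaddexp(0, -t): no overflow for any margin
    loss = float(np.mean(np.logaddexp(0.0, -margins)))
    return loss + lam * float(np.abs(w).sum())


def _loss_grad(w: np.ndarray, v: float, X: np.ndarray,
               y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Smooth part: value, gradient wrt w, gradient wrt v."""
    m = X.shape[0]
    margins = y * (X @ w + v)
    loss = float(np.mean(np.logaddexp(0.0, -margins)))
    # d/dt log(1+e^{-t}) = -sigma(-t)
    s = _sigmoid(-margins)
    coef = -(y * s) / m
    return loss, X.T @ coef, float(coef.sum())


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the zero weight vector is optimal.

    At ``w = 0`` the optimal intercept is ``log(m+/m-)``; the zero vector
    (with that intercept) minimizes the objective iff every coordinate of
    the loss gradient is at most lambda in magnitude.
    """
    y = _check_labels(y)
    m_pos = int(np.sum(y > 0))
    m_neg = int(np.sum(y < 0))
    if m_pos == 0 or m_neg == 0:
        raise ValidationError("both classes must be present")
    v_star = np.log(m_pos / m_neg)
    _, gw, _ = _loss_grad(np.zeros(X.shape[1]), v_star, X, y)
    return float(np.max(np.abs(gw)))


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _kkt_residual(w: np.ndarray, gw: np.ndarray, gv: float,
                  lam: float) -> float:
    """Max violation of the subgradient optimality conditions."""
    res = abs(gv)
    nz = w != 0
    if np.any(nz):
        res = max(res, float(np.max(np.abs(gw[nz] + lam * np.sign(w[nz])))))
    if np.any(~nz):
        res = max(res, float(np.max(np.maximum(np.abs(gw[~nz]) - lam, 0.0))))
    return res


def _fit_arrays(X: np.ndarray, y: np.ndarray, lam: float,
                config: TrainConfig) -> tuple[np.ndarray, float, int, bool]:
    """FISTA with adaptive restart on (w, v); returns (w, v, iters, converged)."""
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values")
    y = _check_labels(y)
    m_pos = int(np.sum(y > 0))
    m_neg = int(np.sum(y < 0))
    if m_pos == 0 or m_neg == 0:
        raise ValidationError("training data must contain both classes")
    if not lam > 0:
        raise ValidationError("lambda must be positive")
    m, d = X.shape
    # Lipschitz constant of the smooth part over (w, v):
    # hessian <= A^T A / (4m) with A = [X, 1]
    A_norm = np.linalg.norm(np.hstack([X, np.ones((m, 1))]), 2)
    L = max(A_norm ** 2 / (4.0 * m), 1e-12)
    step = 1.0 / L

    w = np.zeros(d)
    v = float(np.log(m_pos / m_neg))  # optimal intercept at w = 0
    zw, zv = w.copy(), v  # momentum point
    t_k = 1.0
    prev_obj = logistic_objective(w, v, X, y, lam)
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        _, gw, gv = _loss_grad(zw, zv, X, y)
        w_new = _soft_threshold(zw - step * gw, step * lam)
        v_new = zv - step * gv
        obj = logistic_objective(w_new, v_new, X, y, lam)
        if obj > prev_obj:  # adaptive restart on objective increase
            zw, zv, t_k = w.copy(), v, 1.0
            _, gw, gv = _loss_grad(zw, zv, X, y)
            w_new = _soft_threshold(zw - step * gw, step * lam)
            v_new = zv - step * gv
            obj = logistic_objective(w_new, v_new, X, y, lam)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k)) / 2.0
        zw = w_new + ((t_k - 1.0) / t_next) * (w_new - w)
        zv = v_new + ((t_k - 1.0) / t_next) * (v_new - v)
        w, v, t_k, prev_obj = w_new, v_new, t_next, obj
        if it % 10 == 0 or it == config.max_iterations:
            _, gw, gv = _loss_grad(w, v, X, y)
            if _kkt_residual(w, gw, gv, lam) <= config.tolerance:
                converged = True
                break
    return w, v, it, converged


class L1Logreg:
    """Sparse logistic regression model bound to a dataset.

    Parameters
    ----------
    X, y
        Feature matrix and +1/-1 labels, or use :meth:`from_dataset`.
    layout
        Optional feature layout carried through to the fitted model.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 layout: WindowLayout | None = None) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        if self.X.shape[0] < 2:
            raise ValidationError("need at least two examples")
        self.layout = layout

    @classmethod
    def from_dataset(cls, dataset: WindowedDataset) -> "L1Logreg":
        return cls(dataset.X, dataset.y, layout=dataset.layout)

    def lambda_max(self) -> float:
        return lambda_max(self.X, self.y)

    def fit(self, lam: float,
            config: TrainConfig | None = None) -> "L1LogregResults":
        config = config or TrainConfig()
        w, v, n_iter, converged = _fit_arrays(self.X, self.y, lam, config)
        if self.layout is None:
            model = _BareModel(w=w, v=v, lam=lam)
        else:
            model = L1LogregModel(w=w, v=v, lam=lam, layout=self.layout)
        obj = logistic_objective(w, v, self.X, self.y, lam)
        return L1LogregResults(model=model, objective=obj, n_iter=n_iter,
                               converged=converged, n_obs=self.X.shape[0])


@dataclass
class _BareModel:
    """Fitted parameters without a feature layout (raw-matrix use)."""

    w: np.ndarray
    v: float
    lam: float
    threshold: float = 0.5

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.w))


@dataclass
class L1LogregResults:
    """Fit output: parameters, objective value and convergence diagnostics."""

    model: L1LogregModel | _BareModel
    objective: float
    n_iter: int
    converged: bool
    n_obs: int

    @property
    def params(self) -> np.ndarray:
        return self.model.w

    @property
    def intercept(self) -> float:
        return self.model.v

    @property
    def nnz(self) -> int:
        return self.model.nnz

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_scores(self.model, X)

    def top_weights(self, k: int = 15) -> list[tuple[str, float]]:
        """Nonzero feature slots sorted by |weight| descending."""
        layout = getattr(self.model, "layout", None)
        names = (layout.slot_names() if layout is not None
                 else [f"x{j}" for j in range(self.model.w.shape[0])])
        nz = [(names[j], float(wj)) for j, wj in enumerate(self.model.w)
              if wj != 0.0]
        nz.sort(key=lambda item: (-abs(item[1]), item[0]))
        return nz[:k]

    def summary(self) -> str:
        lines = [
            "L1-regularized logistic regression",
            f"  observations: {self.n_obs}",
            f"  features:     {self.model.w.shape[0]}",
            f"  lambda:       {self.model.lam:g}",
            f"  objective:    {self.objective:.8f}",
            f"  nonzero w:    {self.nnz}",
            f"  intercept:    {self.model.v:.6f}",
            f"  iterations:   {self.n_iter}"
            f" ({'converged' if self.converged else 'NOT converged'})",
            "  top weights:",
        ]
        for name, wj in self.top_weights(15):
            lines.append(f"    {name:<14s} {wj:+.6f}")
        return "\n".join(lines)


def fit(dataset: WindowedDataset, lam: float,
        config: TrainConfig | None = None) -> L1LogregModel:
    """Fit on a windowed dataset and return the bare fitted model."""
    results = L1Logreg.from_dataset(dataset).fit(lam, config)
    return results.model


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Per-row probability of the positive (catalytic) class."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.w.shape[0]:
        raise ValidationError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} "
            f"columns, model expects {model.w.shape[0]}"
        )
    return _sigmoid(X @ model.w + model.v)
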