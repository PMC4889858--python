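"""Proportional-odds (cumulative logit) MLE with analytic gradients.

Parameterization: ``P(y <= k | x) = expit(c_k - x'beta)`` with strictly
increasing cutpoints ``c`` encoded unconstrained as
``c = cumsum([t_0, exp(t_1), ..., exp(t_{K-2})])``.  The likelihood and
gradient are fully vectorised, so fitting scales to cohort-sized panels
(hundreds of thousands of person-quarters), which statsmodels' generic
ordinal model (numeric derivatives) does not; a unit test checks agreement
with statsmodels ``OrderedModel`` on moderate data.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


class OrdinalFitError(RuntimeError):
    pass


def _unpack(params: np.ndarray, p: int):
    beta = params[:p]
    t = params[p:]
    c = np.concatenate([[t[0]], t[0] + np.cumsum(np.exp(t[1:]))]) if t.size > 1 else t[:1].copy()
    return beta, t, c


def _nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, K: int):
    n, p = X.shape
    beta, t, c = _unpack(params, p)
    eta = X @ beta
    cc = np.concatenate([[-np.inf], c, [np.inf]])
    z1 = cc[y + 1] - eta
    z0 = cc[y] - eta
    F1, F0 = expit(z1), expit(z0)
    prob = np.maximum(F1 - F0, 1e-300)
    nll = -np.log(prob).sum()

    f1 = np.where(np.isfinite(z1), F1 * (1.0 - F1), 0.0)
    f0 = np.where(np.isfinite(z0), F0 * (1.0 - F0), 0.0)
    # d ll / d eta = -(f1 - f0)/prob ; d eta / d beta = x
    gbeta = X.T @ ((f1 - f0) / prob)
    # d ll / d c_j accumulates +f1/prob at j = y (y < K-1), -f0/prob at j = y-1
    gc = np.zeros(K - 1)
    upper = y < K - 1
    np.add.at(gc, y[upper], -(f1 / prob)[upper])  # negative log-lik sign
    lower = y > 0
    np.add.at(gc, y[lower] - 1, (f0 / prob)[lower])
    # chain rule through the increasing-cutpoint transform
    gt = np.empty_like(gc)
    rev = np.cumsum(gc[::-1])[::-1]  # sum_{j >= i} gc_j
    gt[0] = rev[0]
    if K > 2:
        gt[1:] = rev[1:] * np.exp(t[1:])
    return nll, np.concatenate([gbeta, gt])


class ProportionalOddsModel:
    """Maximum-likelihood cumulative-logit model for ordered categories.

    ``levels_`` are the observed category codes in increasing order; the
    design matrix must not contain a constant column (the cutpoints play
    that role).
    """

    def __init__(self):
        self.levels_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None
        self.cutpoints_: np.ndarray | None = None
        self.converged_: bool = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ProportionalOddsModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.levels_ = np.unique(y)
        K = self.levels_.size
        if K < 3:
            raise OrdinalFitError("use plain logistic regression for < 3 levels")
        codes = np.searchsorted(self.levels_, y)
        n, p = X.shape
        # standardize internally for optimizer conditioning; map back after
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        freq = np.bincount(codes, minlength=K) / n
        cum = np.clip(np.cumsum(freq)[:-1], 1e-6, 1 - 1e-6)
        c0 = np.log(cum / (1 - cum))
        t0 = np.concatenate([[c0[0]], np.log(np.maximum(np.diff(c0), 1e-3))])
        x0 = np.concatenate([np.zeros(p), t0])
        res = minimize(
            _nll_grad,
            x0,
            args=(Xs, codes, K),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if np.linalg.norm(res.jac, np.inf) / n > 1e-8:
            # restarting resets the L-BFGS memory and reliably drives the
            # gradient a few more orders down once near the optimum
            res = minimize(
                _nll_grad, res.x, args=(Xs, codes, K), jac=True,
                method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-9},
            )
        if np.linalg.norm(res.jac, np.inf) / n > 1e-6:
            raise OrdinalFitError(f"proportional-odds fit did not converge: {res.message}")
        beta_s, _, cut_s = _unpack(res.x, p)
        self.coef_ = beta_s / sd
        self.cutpoints_ = cut_s + float(mu @ self.coef_)
        self.converged_ = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of category probabilities in ``levels_`` order."""
        X = np.asarray(X, dtype=float)
        eta = X @ self.coef_
        cum = expit(self.cutpoints_[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(X), 1)), cum, np.ones((len(X), 1))])
        return np.diff(cum, axis=1)
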