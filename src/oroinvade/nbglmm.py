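"""Negative-binomial (NB2) mixed-model engine with nested Gaussian
random intercepts, estimated by a Laplace approximation.

Random effects are spherical (``u_l = sigma_l * b_l`` with ``b ~ N(0, I)``),
so the objective is smooth at ``sigma = 0`` and boundary fits are
well-defined.  The inner problem maximizes the penalized log-likelihood
jointly over fixed effects and spherical effects by damped Newton (it is
strictly concave in the linear predictor); the outer problem optimizes
``(log theta, sigma_1..L)`` on the Laplace marginal objective.  Fixed-effect
covariance is the corresponding block of the inverse joint Hessian at the
mode, as in standard mixed-model practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special

__all__ = ["NBGlmmResult", "fit_nb_glmm_arrays", "nb2_loglik"]


def nb2_loglik(y: np.ndarray, eta: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood at linear predictor ``eta`` (log link)."""
    mu = np.exp(eta)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (eta - np.log(theta + mu))
        )
    )


@dataclass
class NBGlmmResult:
    beta: np.ndarray
    se: np.ndarray
    theta: float
    sigma: dict
    ranef: dict  # level -> array of u = sigma * b at the mode
    loglik: float  # Laplace marginal log-likelihood
    converged: bool
    n_iter: int
    grad_norm: float
    singular: bool
    n_obs: int
    group_sizes: dict = field(default_factory=dict)
    objective_trace: list = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * special.ndtr(-np.abs(self.zvalues))


class _Inner:
    """Penalized joint Newton solver for fixed ``(theta, sigma)``."""

    def __init__(self, y, X, offset, group_idx, group_sizes):
        self.y = y
        self.X = X
        self.offset = offset
        self.group_idx = group_idx  # list of int arrays, one per level
        self.group_sizes = group_sizes  # list of q_l
        self.n, self.p = X.shape
        self.q = int(sum(group_sizes))
        self.w = np.zeros(self.p + self.q)  # warm start: (beta, b)

    def eta(self, w, sigma):
        beta = w[: self.p]
        eta = self.offset + self.X @ beta
        pos = self.p
        for g, q_l, s in zip(self.group_idx, self.group_sizes, sigma):
            eta = eta + s * w[pos + g]
            pos += q_l
        return eta

    def _score_weight(self, eta, theta):
        mu = np.exp(eta)
        score = self.y - (self.y + theta) * mu / (theta + mu)
        wgt = (self.y + theta) * theta * mu / (theta + mu) ** 2
        return score, np.maximum(wgt, 1e-12)

    def _objective(self, w, sigma, theta):
        b = w[self.p :]
        return nb2_loglik(self.y, self.eta(w, sigma), theta) - 0.5 * float(b @ b)

    def _assemble(self, score, wgt, sigma):
        """Gradient and Hessian of the penalized objective at current w."""
        p, q = self.p, self.q
        dim = p + q
        grad = np.empty(dim)
        H = np.zeros((dim, dim))
        X = self.X
        Xw = X * wgt[:, None]
        grad[:p] = X.T @ score
        H[:p, :p] = X.T @ Xw
        offs = [p]
        for q_l in self.group_sizes:
            offs.append(offs[-1] + q_l)
        for a, (ga, qa, sa) in enumerate(zip(self.group_idx, self.group_sizes, sigma)):
            ia = offs[a]
            grad[ia : ia + qa] = sa * np.bincount(ga, weights=score, minlength=qa)
            # X' W Z_a, one bincount per fixed-effect column
            M = np.empty((qa, self.p))
            for j in range(self.p):
                M[:, j] = np.bincount(ga, weights=Xw[:, j], minlength=qa)
            H[:p, ia : ia + qa] = sa * M.T
            H[ia : ia + qa, :p] = sa * M
            for b, (gb, qb, sb) in enumerate(zip(self.group_idx, self.group_sizes, sigma)):
                if b < a:
                    continue
                ib = offs[b]
                ZZ = np.bincount(ga * qb + gb, weights=wgt, minlength=qa * qb).reshape(qa, qb)
                H[ia : ia + qa, ib : ib + qb] += sa * sb * ZZ
                if b != a:
                    H[ib : ib + qb, ia : ia + qa] += sa * sb * ZZ.T
        # penalty on b
        H[p:, p:] += np.eye(q)
        grad[p:] -= self.w_b
        return grad, H

    def solve(self, sigma, theta, tol=1e-6, max_iter=60):
        w = self.w.copy()
        obj = self._objective(w, sigma, theta)
        grad_norm = np.inf
        for it in range(max_iter):
            eta = self.eta(w, sigma)
            score, wgt = self._score_weight(eta, theta)
            self.w_b = w[self.p :]
            grad, H = self._assemble(score, wgt, sigma)
            grad_norm = float(np.max(np.abs(grad)))
            if grad_norm < tol:
                break
            try:
                c, low = linalg.cho_factor(H, check_finite=False)
                step = linalg.cho_solve((c, low), grad, check_finite=False)
            except linalg.LinAlgError:
                step = linalg.solve(H + 1e-6 * np.eye(H.shape[0]), grad, assume_a="pos")
            # damped Newton: halve until the objective does not decrease
            t = 1.0
            for _ in range(30):
                w_new = w + t * step
                obj_new = self._objective(w_new, sigma, theta)
                if np.isfinite(obj_new) and obj_new >= obj - 1e-10:
                    break
                t *= 0.5
            if obj_new < obj - 1e-8:  # no ascent possible
                break
            w, obj = w_new, obj_new
        self.w = w  # warm start for the next outer evaluation
        eta = self.eta(w, sigma)
        score, wgt = self._score_weight(eta, theta)
        self.w_b = w[self.p :]
        grad, H = self._assemble(score, wgt, sigma)
        return w, obj, H, float(np.max(np.abs(grad))), it + 1


def _laplace_objective(inner: _Inner, sigma, theta):
    w, obj, H, gnorm, n_iter = inner.solve(sigma, theta)
    p = inner.p
    H_bb = H[p:, p:]
    sign, logdet = np.linalg.slogdet(H_bb)
    if sign <= 0:
        return -np.inf, (w, H, gnorm, n_iter)
    return obj - 0.5 * logdet, (w, H, gnorm, n_iter)


def fit_nb_glmm_arrays(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    groups: dict,
    theta0: float = 1.0,
    sigma0: float = 0.3,
    singular_tol: float = 1e-3,
) -> NBGlmmResult:
    """Fit the NB2 mixed model on prepared arrays.

    ``groups`` maps level name → integer codes array (0..q_l−1) per
    observation; levels are integrated as independent spherical
    intercepts (nesting is encoded by the codes themselves).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    level_names = list(groups)
    group_idx = [np.asarray(groups[k], dtype=np.intp) for k in level_names]
    group_sizes = [int(g.max()) + 1 if g.size else 0 for g in group_idx]
    inner = _Inner(y, X, offset, group_idx, group_sizes)

    trace: list[float] = []
    best = {"obj": -np.inf}

    def negobj(phi):
        theta = float(np.exp(phi[0]))
        sigma = np.abs(phi[1:])
        val, aux = _laplace_objective(inner, sigma, theta)
        if val > best["obj"]:
            best.update(obj=val, phi=phi.copy(), aux=aux, sigma=sigma, theta=theta)
        trace.append(best["obj"])
        return -val

    phi0 = np.concatenate([[np.log(theta0)], np.full(len(level_names), sigma0)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            negobj,
            phi0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-3, "maxfev": 100 * (1 + len(level_names))},
        )
    # evaluate once more at the optimizer's solution to refresh inner state
    negobj(res.x)
    phi = best["phi"]
    theta = best["theta"]
    sigma = best["sigma"]
    w, H, gnorm, n_iter = best["aux"]
    p = inner.p
    try:
        cov = linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except linalg.LinAlgError:
        se = np.full(p, np.nan)

    ranef = {}
    pos = p
    for name, q_l, s in zip(level_names, group_sizes, sigma):
        ranef[name] = s * w[pos : pos + q_l]
        pos += q_l

    return NBGlmmResult(
        beta=w[:p].copy(),
        se=se,
        theta=theta,
        sigma={k: float(s) for k, s in zip(level_names, sigma)},
        ranef=ranef,
        loglik=float(best["obj"]),
        converged=bool(res.success and gnorm < 1e-3),
        n_iter=int(n_iter),
        grad_norm=float(gnorm),
        singular=bool(np.any(sigma < singular_tol)),
        n_obs=int(y.size),
        group_sizes={k: q for k, q in zip(level_names, group_sizes)},
        objective_trace=trace,
    )
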