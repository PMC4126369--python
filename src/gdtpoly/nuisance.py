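"""Pooled polytomous (multinomial) logistic fits for nuisance coefficients.

The pair weights of the conditional score tests require estimates of the
coefficients of a polytomous logistic model of the outcome on the free
predictors.  With an independence working correlation, the generalized
estimating equations coincide with the pooled multinomial likelihood score,
so the point estimates are the pooled maximum-likelihood fit; family
structure is deliberately ignored here (it matters only for the comparator
Wald variances, which use a family-clustered sandwich).

Fitting is damped Newton on the pooled multinomial log-likelihood with
analytic gradient and Hessian; on non-convergence or a singular Hessian the
fit falls back to a small ridge penalty (1e-6) with a logged warning.
Variability of these estimates is neglected downstream: the weights treat
them as fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .design import TERM_FUNCS, DesignSpec

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


@dataclass
class PolytomousFit:
    """Result of a pooled multinomial-logit fit on a DesignSpec.

    Parameters are the K-1 category intercepts followed by one coefficient
    per label (reference category K fixed at zero).  ``obs_scores`` holds the
    per-observation score vectors and ``information`` the observed
    information at the optimum, for downstream sandwich variances.
    """

    spec: DesignSpec
    param_names: tuple[str, ...]
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    obs_scores: np.ndarray        # (n, p)
    information: np.ndarray       # (p, p), without ridge
    ridge: float = 0.0

    @property
    def intercepts(self) -> np.ndarray:
        return self.theta[: self.spec.K - 1]

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.spec.labels, self.theta[self.spec.K - 1:]))

    def slope_array(self) -> np.ndarray:
        """(K, q) slopes on the distinct free-predictor functions.

        Row k-1 holds category k's coefficient on each function of
        ``spec.funcs`` (0 when the category has no such term); the reference
        row K is all zeros.  Intercepts never enter pair weights: they cancel
        in the predictor difference.
        """
        q = len(self.spec.funcs)
        A = np.zeros((self.spec.K, q))
        coef = self.coef
        for t in self.spec.terms:
            A[t.category - 1, self.spec.funcs.index(t.func)] = coef[t.label]
        return A

    def free_predictors(self, x1, x2) -> np.ndarray:
        """(n, q) values of the distinct free-predictor functions."""
        cols = [
            TERM_FUNCS[f](
                x1 if x1 is not None else 0.0, x2 if x2 is not None else 0.0
            )
            for f in self.spec.funcs
        ]
        return np.column_stack(cols) if cols else np.zeros((np.size(x1), 0))


def predictor_tensor(spec: DesignSpec, x1, x2) -> tuple[np.ndarray, tuple[str, ...]]:
    """Build Z with Z[i, k, p] = d(linear predictor of category k+1)/d(theta_p)."""
    n = np.size(x1) if x1 is not None else np.size(x2)
    Km1 = spec.K - 1
    labels = spec.labels
    p = Km1 + len(labels)
    Z = np.zeros((n, Km1, p))
    for k in range(Km1):
        Z[:, k, k] = 1.0
    cols = spec.term_columns(x1, x2)
    for t in spec.terms:
        Z[:, t.category - 1, Km1 + labels.index(t.label)] = cols[t.label]
    names = tuple(f"mu{k}" for k in range(1, spec.K)) + labels
    return Z, names


def _loglik_parts(Z: np.ndarray, yidx: np.ndarray, theta: np.ndarray):
    eta = Z @ theta                                   # (n, K-1)
    eta_full = np.concatenate([eta, np.zeros((eta.shape[0], 1))], axis=1)
    m = logsumexp(eta_full, axis=1)
    ll = float(eta_full[np.arange(len(yidx)), yidx].sum() - m.sum())
    P = np.exp(eta - m[:, None])                      # (n, K-1)
    return ll, P


def fit_polytomous(
    y: np.ndarray,
    x1,
    x2,
    spec: DesignSpec,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol_grad: float = 1e-8,
    tol_ll: float = 1e-10,
    _allow_fallback: bool = True,
) -> PolytomousFit:
    """Damped-Newton pooled multinomial-logit fit of y (1..K) on a design.

    Deterministic given the data order.  Raises :class:`FitError` when some
    outcome category is empty; complete separation triggers the ridge
    fallback instead of failing.
    """
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=spec.K + 1)[1: spec.K + 1]
    if (counts == 0).any():
        empty = [k + 1 for k in range(spec.K) if counts[k] == 0]
        raise FitError(f"empty outcome category {empty}")
    Z, names = predictor_tensor(spec, x1, x2)
    n, Km1, p = Z.shape
    yind = np.zeros((n, Km1))
    yidx = y - 1
    inref = yidx < Km1
    yind[np.flatnonzero(inref), yidx[inref]] = 1.0

    theta = np.zeros(p)
    ll, P = _loglik_parts(Z, yidx, theta)
    ll -= 0.5 * ridge * theta @ theta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = yind - P
        g = np.einsum("ik,ikp->p", resid, Z) - ridge * theta
        if np.max(np.abs(g)) < tol_grad:
            converged = True
            break
        H = np.einsum("ik,ikp,ikq->pq", P, Z, Z) - np.einsum(
            "ik,ikp,il,ilq->pq", P, Z, P, Z
        )
        H += ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            if ridge == 0.0 and _allow_fallback:
                logger.warning(
                    "singular information in multinomial fit; refitting with "
                    "ridge penalty 1e-6"
                )
                return fit_polytomous(
                    y, x1, x2, spec, ridge=1e-6, max_iter=max_iter,
                    tol_grad=tol_grad, tol_ll=tol_ll, _allow_fallback=False,
                )
            raise FitError("singular information matrix") from None
        # step-halving line search on the penalized log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            ll_new, P_new = _loglik_parts(Z, yidx, cand)
            ll_new -= 0.5 * ridge * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if abs(ll_new - ll) <= tol_ll * (abs(ll) + 1.0):
            theta, ll, P = cand, ll_new, P_new
            converged = True
            break
        theta, ll, P = cand, ll_new, P_new
    # complete separation drives coefficients to +/- infinity while the
    # likelihood flattens; cap via the ridge fallback
    separated = np.max(np.abs(theta)) > 15.0
    if (not converged or separated) and ridge == 0.0 and _allow_fallback:
        logger.warning(
            "multinomial fit did not converge cleanly (possible complete "
            "separation); refitting with ridge penalty 1e-6"
        )
        return fit_polytomous(
            y, x1, x2, spec, ridge=1e-6, max_iter=max_iter,
            tol_grad=tol_grad, tol_ll=tol_ll, _allow_fallback=False,
        )

    resid = yind - P
    obs_scores = np.einsum("ik,ikp->ip", resid, Z)
    info = np.einsum("ik,ikp,ikq->pq", P, Z, Z) - np.einsum(
        "ik,ikp,il,ilq->pq", P, Z, P, Z
    )
    return PolytomousFit(
        spec=spec,
        param_names=names,
        theta=theta,
        loglik=ll,
        converged=converged,
        n_iter=it,
        n_obs=n,
        obs_scores=obs_scores,
        information=info,
        ridge=ridge,
    )


def fit_alpha(samples, spec: DesignSpec, **kwargs) -> PolytomousFit:
    """Fit nuisance coefficients on data stacked across families.

    ``samples`` is an iterable of :class:`~gdtpoly.pedio.FamilySample`; the
    fit pools all retained members (independence working correlation).
    """
    ys, x1s, x2s = [], [], []
    for s in samples:
        ys.append(s.y)
        x1s.append(s.x1 if s.x1 is not None else np.zeros(s.n))
        x2s.append(s.x2 if s.x2 is not None else np.zeros(s.n))
    y = np.concatenate(ys)
    x1 = np.concatenate(x1s) if spec.requires_x1 else None
    x2 = np.concatenate(x2s) if spec.requires_x2 else None
    return fit_polytomous(y, x1, x2, spec, **kwargs)
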