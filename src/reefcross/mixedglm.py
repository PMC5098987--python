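"""Maximum-likelihood GLMMs with crossed Gaussian random effects.

Supports log-link Poisson (with an optional observation-level random effect
for overdispersion) and negative-binomial (NB2) responses, with any number of
crossed random-intercept terms.  The marginal likelihood integrates the
random effects out by a Laplace approximation at the joint mode; because the
penalized log-likelihood is concave in the random effects for both families,
the inner Newton solve is globally convergent.  For models whose total random
dimension is small the Laplace approximation can be refined by tensor-product
adaptive Gauss-Hermite quadrature centred and scaled at the mode, which is
the accuracy reference used by the test oracles.

Variance parameters are optimized on the standard-deviation scale, bounded
below at zero, so singular (zero-variance) fits are admissible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.special import gammaln, logsumexp

__all__ = ["RandomTerm", "MixedModelFit", "marginal_loglik", "fit_mixed_glm",
           "indicator_matrix"]

_SD_FLOOR = 1e-6  # below this a random term is treated as absent


def indicator_matrix(labels) -> tuple[np.ndarray, list]:
    """Dense 0/1 design matrix for a categorical vector, plus its levels."""
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    Z = np.zeros((len(labels), len(levels)))
    index = {lv: j for j, lv in enumerate(levels)}
    for i, lab in enumerate(labels):
        Z[i, index[lab]] = 1.0
    return Z, levels


@dataclass
class RandomTerm:
    """A random-intercept term: name plus its n x q indicator matrix."""

    name: str
    Z: np.ndarray

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class MixedModelFit:
    family: str
    fixed_effects: dict[str, tuple[float, float]]
    random_variances: dict[str, float]
    nb_dispersion: float | None
    log_likelihood: float
    converged: bool
    n_obs: int
    n_params: int
    mean_linear_predictor: float = 0.0
    mean_mu: float = 0.0
    fixed_predictor_variance: float = 0.0
    fixed_names: list[str] = field(default_factory=list)
    beta: np.ndarray | None = None
    beta_cov: np.ndarray | None = None

    @property
    def aicc(self) -> float:
        k, n = self.n_params, self.n_obs
        aic = -2.0 * self.log_likelihood + 2.0 * k
        if n - k - 1 > 0:
            aic += 2.0 * k * (k + 1) / (n - k - 1)
        return aic


# ---------------------------------------------------------------------------
# per-observation log-likelihood and its first two derivatives in eta
# ---------------------------------------------------------------------------

def _poisson_parts(y, eta):
    mu = np.exp(np.minimum(eta, 300.0))
    ll = y * eta - mu - gammaln(y + 1.0)
    return ll, y - mu, mu


def _nb_parts(y, eta, theta):
    mu = np.exp(np.minimum(eta, 300.0))
    ll = (
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
        + theta * np.log(theta) + y * eta - (y + theta) * np.log(mu + theta)
    )
    grad = y - (y + theta) * mu / (mu + theta)
    curv = (y + theta) * theta * mu / (mu + theta) ** 2
    return ll, grad, curv


def _loglik_parts(y, eta, family, theta):
    if family.startswith("poisson"):
        return _poisson_parts(y, eta)
    if family == "negative_binomial":
        return _nb_parts(y, eta, theta)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# inner problem: joint mode of the random effects
# ---------------------------------------------------------------------------

def _active_terms(terms, variances):
    act = [(t, v) for t, v in zip(terms, variances) if v > _SD_FLOOR**2]
    return act


def _joint_mode(y, eta_fixed, Z, prec, family, theta, u0=None,
                tol=1e-8, max_iter=40):
    """Newton maximization of the penalized log-likelihood over u.

    ``Z`` is the concatenated indicator matrix of the active terms and
    ``prec`` the diagonal of the prior precision.  The objective is concave,
    so Newton with step halving converges globally.
    """
    q = Z.shape[1]
    u = np.zeros(q) if u0 is None or len(u0) != q else u0.copy()

    def objective(u):
        ll, _, _ = _loglik_parts(y, eta_fixed + Z @ u, family, theta)
        return float(ll.sum() - 0.5 * np.dot(u * prec, u))

    f = objective(u)
    H = None
    for _ in range(max_iter):
        eta = eta_fixed + Z @ u
        _, g_eta, w_eta = _loglik_parts(y, eta, family, theta)
        grad = Z.T @ g_eta - prec * u
        H = (Z.T * w_eta) @ Z
        H[np.diag_indices(q)] += prec
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            f_new = objective(u + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        if t * np.max(np.abs(step)) < 1e-11:  # no usable progress left
            u = u + t * step
            f = f_new
            break
        u = u + t * step
        f = f_new
    if H is None:
        eta = eta_fixed + Z @ u
        _, _, w_eta = _loglik_parts(y, eta, family, theta)
        H = (Z.T * w_eta) @ Z
        H[np.diag_indices(q)] += prec
    return u, f, H


def _logdet_spd(H):
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("Hessian not positive definite")
    return logdet


def marginal_loglik(
    y,
    X,
    beta,
    terms: list[RandomTerm],
    variances,
    family: str = "poisson",
    theta: float | None = None,
    method: str = "laplace",
    ghq_order: int = 9,
    u0=None,
    return_mode: bool = False,
):
    """Marginal log-likelihood with the random effects integrated out.

    ``variances`` aligns with ``terms``; terms with (near-)zero variance are
    dropped from the integral.  ``method`` is ``"laplace"`` or ``"aghq"``
    (tensor-product adaptive Gauss-Hermite at the mode; total grid size is
    capped, so it is meant for the small models used as accuracy oracles).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    eta_fixed = X @ beta
    active = _active_terms(terms, variances)
    if not active:
        ll, _, _ = _loglik_parts(y, eta_fixed, family, theta)
        out = float(ll.sum())
        return (out, np.zeros(0), eta_fixed) if return_mode else out

    Z = np.hstack([t.Z for t, _ in active])
    prec = np.concatenate([np.full(t.q, 1.0 / v) for t, v in active])
    u_hat, f_hat, H = _joint_mode(y, eta_fixed, Z, prec, family, theta, u0=u0)
    q = Z.shape[1]
    log_prior_norm = -0.5 * q * np.log(2.0 * np.pi) + 0.5 * np.sum(np.log(prec))

    if method == "laplace":
        logL = f_hat + log_prior_norm + 0.5 * q * np.log(2.0 * np.pi) \
            - 0.5 * _logdet_spd(H)
    elif method == "aghq":
        if ghq_order**q > 3_000_000:
            raise ValueError(
                f"tensor AGHQ infeasible: {ghq_order}^{q} nodes; use laplace"
            )
        nodes, weights = special.roots_hermite(ghq_order)
        L = np.linalg.cholesky(H)
        Linv_t = np.linalg.inv(L).T
        grids = np.meshgrid(*([nodes] * q), indexing="ij")
        x = np.stack([g.ravel() for g in grids], axis=1)  # (m, q)
        logw = np.log(weights)
        wgrids = np.meshgrid(*([logw] * q), indexing="ij")
        logW = np.sum(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
        U = u_hat[None, :] + np.sqrt(2.0) * x @ Linv_t.T
        eta = eta_fixed[None, :] + U @ Z.T
        ll, _, _ = _loglik_parts(y[None, :], eta, family, theta)
        f_vals = ll.sum(axis=1) - 0.5 * np.sum(U * U * prec[None, :], axis=1)
        log_integral = (
            0.5 * q * np.log(2.0)
            - 0.5 * _logdet_spd(H)
            + logsumexp(logW + f_vals + np.sum(x * x, axis=1))
        )
        logL = log_prior_norm + log_integral
    else:
        raise ValueError(f"unknown method {method!r}")
    if return_mode:
        return float(logL), u_hat, eta_fixed + Z @ u_hat
    return float(logL)


# ---------------------------------------------------------------------------
# outer maximum-likelihood fit
# ---------------------------------------------------------------------------

def fit_mixed_glm(
    y,
    X,
    terms: list[RandomTerm],
    family: str = "poisson",
    fixed_names: list[str] | None = None,
    olre: bool = False,
    start_sd: float = 0.3,
    compute_beta_cov: bool = True,
    maxiter: int = 100,
) -> MixedModelFit:
    """Fit a mixed GLM by maximizing the profiled Laplace marginal likelihood.

    The fixed effects are profiled out inside the (concave) joint Newton
    solve together with the random-effect modes, so the outer optimization
    runs only over the variance parameters (standard deviations, bounded
    below at zero) and, for negative-binomial models, the log dispersion.
    ``olre=True`` appends an observation-level random effect (one level per
    row) to a Poisson model, the standard device for overdispersed counts.
    Non-convergence is flagged on the returned fit, never silently ignored.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    terms = list(terms)
    family_label = family
    if olre:
        if family != "poisson":
            raise ValueError("observation-level effects are for Poisson models")
        terms.append(RandomTerm("observation", np.eye(n)))
        family_label = "poisson_olre"
    k = len(terms)
    is_nb = family == "negative_binomial"
    if fixed_names is None:
        fixed_names = [f"beta{j}" for j in range(p)]

    state: dict = {}

    def unpack(x):
        x = np.asarray(x, dtype=float).copy()
        x[:k] = np.clip(np.abs(x[:k]), 0.0, 20.0)
        sds = x[:k]
        theta = float(np.exp(np.clip(x[k], -4.0, 8.0))) if is_nb else None
        return sds**2, theta

    def profiled(x, want_all=False):
        """Profiled Laplace log-likelihood at variance parameters x."""
        variances, theta = unpack(x)
        active = [(t, v) for t, v in zip(terms, variances) if v > _SD_FLOOR**2]
        Zfull = np.hstack([X] + [t.Z for t, _ in active]) if active else X
        prec = np.concatenate(
            [np.zeros(p)] + [np.full(t.q, 1.0 / v) for t, v in active]
        ) if active else np.zeros(p)
        bu, f, H = _joint_mode(
            y, np.zeros(n), Zfull, prec, family, theta,
            u0=state.get("bu") if state.get("dim") == Zfull.shape[1] else None,
        )
        state["bu"], state["dim"] = bu, Zfull.shape[1]
        if active:
            logdet_uu = _logdet_spd(H[p:, p:])
            logL = f + 0.5 * np.sum(np.log(prec[p:])) - 0.5 * logdet_uu
        else:
            logL = f
        if want_all:
            return logL, bu, H, Zfull
        return logL

    def negloglik(x):
        fail = 1e10 + 1e4 * float(np.sum(np.square(x)))
        try:
            ll = profiled(x)
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return fail
        return -ll if np.isfinite(ll) else fail

    x0 = np.concatenate([np.full(k, start_sd), [np.log(2.0)] if is_nb else []])
    bounds = [(0.0, 20.0)] * k + ([(-4.0, 8.0)] if is_nb else [])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if len(x0):
            res = optimize.minimize(
                negloglik, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": min(maxiter, 50), "ftol": 1e-10,
                         "gtol": 1e-6, "eps": 1e-5},
            )
            # polish with a simplex search; the finite-difference gradient
            # stalls near the sd >= 0 boundary where the objective is flat
            x_start = res.x if np.isfinite(res.fun) else x0
            res2 = optimize.minimize(
                negloglik, x_start, method="Nelder-Mead",
                options={"maxiter": 80 * len(x0), "fatol": 1e-8,
                         "xatol": 1e-6},
            )
            if np.isfinite(res2.fun) and (res2.fun < res.fun or not res.success):
                best = res2
            else:
                best = res
            best_success = bool(res.success or res2.success) and best.fun < 1e9
            x_best = np.asarray(best.x, dtype=float)
        else:  # no variance parameters at all: plain GLM via one inner solve
            x_best = x0
            best_success = True

    variances, theta = unpack(x_best)
    state.clear()
    ll, bu, H, Zfull = profiled(x_best, want_all=True)
    beta = bu[:p]
    eta_hat = Zfull @ bu
    mu_hat = np.exp(np.minimum(eta_hat, 300.0))

    beta_cov = None
    se = np.full(p, np.nan)
    if compute_beta_cov:
        try:
            beta_cov = np.linalg.inv(H)[:p, :p]
            se = np.sqrt(np.clip(np.diag(beta_cov), 0.0, None))
        except np.linalg.LinAlgError:
            beta_cov = None

    fixed_part = X @ beta - (X[:, :1] @ beta[:1] if _has_intercept(X) else 0.0)
    fit = MixedModelFit(
        family=family_label,
        fixed_effects={nm: (float(b), float(s)) for nm, b, s in zip(fixed_names, beta, se)},
        random_variances={t.name: float(v) for t, v in zip(terms, variances)},
        nb_dispersion=theta,
        log_likelihood=float(ll),
        converged=bool(np.isfinite(ll)) and best_success,
        n_obs=n,
        n_params=p + k + (1 if is_nb else 0),
        mean_linear_predictor=float(np.mean(eta_hat)),
        mean_mu=float(np.mean(mu_hat)),
        fixed_predictor_variance=float(np.var(np.asarray(fixed_part).ravel())),
        fixed_names=list(fixed_names),
        beta=np.asarray(beta).copy(),
        beta_cov=beta_cov,
    )
    if not fit.converged:
        warnings.warn("mixed-model fit did not converge", stacklevel=2)
    return fit


def _has_intercept(X) -> bool:
    return np.allclose(X[:, 0], 1.0)
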