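"""Moderated nonlinear factor analysis (MNLFA) for a 7-item unidimensional scale.

Model
-----
For person *i* with covariate vector :math:`x_i` (here the five Helmert contrast
codes) and item responses :math:`y_i \\in \\mathbb{R}^7`:

.. math::

    \\eta_i \\sim N(\\alpha(x_i), \\psi(x_i)), \\qquad
    y_{ij} = \\nu_j(x_i) + \\lambda_j(x_i)\\,\\eta_i + \\epsilon_{ij},
    \\qquad \\epsilon_{ij} \\sim N(0, \\theta_j)

with moderated parameter maps

.. math::

    \\alpha(x) = \\beta^\\top x, \\quad
    \\psi(x) = \\exp(\\delta^\\top x), \\quad
    \\nu_j(x) = \\nu_{j0} + \\kappa_j^\\top x, \\quad
    \\lambda_j(x) = \\lambda_{j0} + \\omega_j^\\top x.

Identification fixes the baseline (x = 0) factor mean at 0 and variance at 1; all
seven baseline loadings are free.  Indicators are treated as continuous, so the
marginal distribution of :math:`y_i` is multivariate normal with

.. math::

    \\mu(x) = \\nu(x) + \\lambda(x)\\alpha(x), \\qquad
    \\Sigma(x) = \\psi(x)\\,\\lambda(x)\\lambda(x)^\\top + \\mathrm{diag}(\\theta),

and the likelihood is available in closed form.  Because the covariates take only a
handful of distinct values (six cells), the log-likelihood is evaluated from
per-pattern sufficient statistics and the rank-one structure of
:math:`\\Sigma(x)` (Sherman–Morrison / matrix determinant lemma), which makes a fit
at n ~ 10,000 essentially independent of n.

Estimation is quasi-Newton (L-BFGS-B) on the packed free-parameter vector with
finite-difference gradients; standard errors come from the numerically
differentiated observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

__all__ = [
    "N_ITEMS",
    "N_COVARIATES",
    "ActiveSet",
    "MNLFAParameters",
    "FitResult",
    "moderated_item_params",
    "marginal_moments",
    "log_likelihood",
    "fit_mnlfa",
    "wald_tests",
    "posterior_factor_score",
    "coefficient_omega",
    "ITEM_COLUMNS",
]

N_ITEMS = 7
N_COVARIATES = 5
ITEM_COLUMNS = tuple(f"item_{j}" for j in range(1, N_ITEMS + 1))
_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ActiveSet:
    """Boolean masks over the moderation blocks (True = freely estimated)."""

    beta: np.ndarray  # (5,)
    delta: np.ndarray  # (5,)
    kappa: np.ndarray  # (7, 5)
    omega_mod: np.ndarray  # (7, 5)

    @classmethod
    def none(cls, n_items: int = N_ITEMS, n_cov: int = N_COVARIATES) -> "ActiveSet":
        return cls(
            beta=np.zeros(n_cov, dtype=bool),
            delta=np.zeros(n_cov, dtype=bool),
            kappa=np.zeros((n_items, n_cov), dtype=bool),
            omega_mod=np.zeros((n_items, n_cov), dtype=bool),
        )

    @classmethod
    def all(cls, n_items: int = N_ITEMS, n_cov: int = N_COVARIATES) -> "ActiveSet":
        return cls(
            beta=np.ones(n_cov, dtype=bool),
            delta=np.ones(n_cov, dtype=bool),
            kappa=np.ones((n_items, n_cov), dtype=bool),
            omega_mod=np.ones((n_items, n_cov), dtype=bool),
        )

    def copy(self) -> "ActiveSet":
        return ActiveSet(
            beta=self.beta.copy(),
            delta=self.delta.copy(),
            kappa=self.kappa.copy(),
            omega_mod=self.omega_mod.copy(),
        )

    @property
    def n_active(self) -> int:
        return int(
            self.beta.sum() + self.delta.sum() + self.kappa.sum() + self.omega_mod.sum()
        )


@dataclass
class MNLFAParameters:
    """Full MNLFA parameter set (baseline + moderation blocks + active mask)."""

    nu0: np.ndarray  # (7,)
    lambda0: np.ndarray  # (7,)
    theta: np.ndarray  # (7,) > 0
    kappa: np.ndarray  # (7, 5)
    omega_mod: np.ndarray  # (7, 5)
    beta: np.ndarray  # (5,)
    delta: np.ndarray  # (5,)
    active: ActiveSet = field(default_factory=ActiveSet.none)

    def __post_init__(self) -> None:
        self.nu0 = np.asarray(self.nu0, dtype=float)
        self.lambda0 = np.asarray(self.lambda0, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.omega_mod = np.asarray(self.omega_mod, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.theta <= 0):
            raise ValueError("uniquenesses theta must be strictly positive")

    @property
    def n_items(self) -> int:
        return self.nu0.shape[0]

    @property
    def n_cov(self) -> int:
        return self.beta.shape[0]

    @classmethod
    def baseline(
        cls,
        nu0,
        lambda0,
        theta,
        n_cov: int = N_COVARIATES,
        active: ActiveSet | None = None,
    ) -> "MNLFAParameters":
        """All moderation blocks zero."""
        nu0 = np.asarray(nu0, dtype=float)
        p = nu0.shape[0]
        return cls(
            nu0=nu0,
            lambda0=np.asarray(lambda0, dtype=float),
            theta=np.asarray(theta, dtype=float),
            kappa=np.zeros((p, n_cov)),
            omega_mod=np.zeros((p, n_cov)),
            beta=np.zeros(n_cov),
            delta=np.zeros(n_cov),
            active=active if active is not None else ActiveSet.none(p, n_cov),
        )

    def copy(self) -> "MNLFAParameters":
        return MNLFAParameters(
            nu0=self.nu0.copy(),
            lambda0=self.lambda0.copy(),
            theta=self.theta.copy(),
            kappa=self.kappa.copy(),
            omega_mod=self.omega_mod.copy(),
            beta=self.beta.copy(),
            delta=self.delta.copy(),
            active=self.active.copy(),
        )

    def zero_inactive(self) -> "MNLFAParameters":
        """Return a copy with inactive moderation entries forced to exactly 0."""
        out = self.copy()
        out.beta[~out.active.beta] = 0.0
        out.delta[~out.active.delta] = 0.0
        out.kappa[~out.active.kappa] = 0.0
        out.omega_mod[~out.active.omega_mod] = 0.0
        return out


# ---------------------------------------------------------------------------
# moderated maps and marginal moments
# ---------------------------------------------------------------------------


def moderated_item_params(params: MNLFAParameters, x: np.ndarray):
    """Evaluate the moderated parameter maps at covariate vector ``x``.

    Returns ``(nu_x, lambda_x, alpha_x, psi_x)`` where the first two are
    length-``n_items`` vectors.
    """
    x = np.asarray(x, dtype=float)
    nu_x = params.nu0 + params.kappa @ x
    lam_x = params.lambda0 + params.omega_mod @ x
    alpha_x = float(params.beta @ x)
    psi_x = float(np.exp(params.delta @ x))
    return nu_x, lam_x, alpha_x, psi_x


def marginal_moments(params: MNLFAParameters, x: np.ndarray):
    """Model-implied mean vector and covariance matrix of the responses at ``x``."""
    nu_x, lam_x, alpha_x, psi_x = moderated_item_params(params, x)
    mu = nu_x + lam_x * alpha_x
    sigma = psi_x * np.outer(lam_x, lam_x) + np.diag(params.theta)
    return mu, sigma


# ---------------------------------------------------------------------------
# sufficient statistics per covariate pattern
# ---------------------------------------------------------------------------


@dataclass
class _PatternStats:
    x: np.ndarray  # (q,) covariate pattern
    n: float  # (weighted) count
    ybar: np.ndarray  # (p,)
    S: np.ndarray  # (p, p) MLE covariance about ybar (divisor n)


def _pattern_stats(Y: np.ndarray, X: np.ndarray) -> list[_PatternStats]:
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("responses and design must be row-aligned 2-d arrays")
    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    out = []
    for g in range(patterns.shape[0]):
        idx = inverse == g
        Yg = Y[idx]
        n = Yg.shape[0]
        ybar = Yg.mean(axis=0)
        D = Yg - ybar
        S = (D.T @ D) / n
        out.append(_PatternStats(x=patterns[g], n=float(n), ybar=ybar, S=S))
    return out


def _pattern_loglik(
    mu: np.ndarray, lam: np.ndarray, psi: float, theta: np.ndarray, st: _PatternStats
) -> float:
    """Gaussian log-likelihood contribution of one covariate pattern.

    Uses the rank-one structure Sigma = psi * lam lam' + diag(theta):
    matrix-determinant lemma for log|Sigma| and Sherman–Morrison for the
    quadratic/trace terms.
    """
    p = theta.shape[0]
    dinv = 1.0 / theta
    a = lam * dinv  # D^{-1} lam
    denom = 1.0 + psi * float(lam @ a)
    logdet = float(np.log(theta).sum()) + np.log(denom)
    c = psi / denom
    Sa = st.S @ a
    tr_term = float(dinv @ np.diag(st.S)) - c * float(a @ Sa)
    d = st.ybar - mu
    quad = float(d * d @ dinv) - c * float(a @ d) ** 2
    return -0.5 * st.n * (p * _LOG2PI + logdet + tr_term + quad)


def _loglik_from_stats(params: MNLFAParameters, stats_list: list[_PatternStats]) -> float:
    total = 0.0
    for st in stats_list:
        nu_x, lam_x, alpha_x, psi_x = moderated_item_params(params, st.x)
        mu = nu_x + lam_x * alpha_x
        total += _pattern_loglik(mu, lam_x, psi_x, params.theta, st)
    return total


def log_likelihood(params: MNLFAParameters, table, design) -> float:
    """Marginal log-likelihood of a response table under ``params``.

    ``table`` may be a DataFrame with ``item_1..item_7`` columns or an (n, 7)
    array; ``design`` a :class:`~pdsmeq.contrasts.ContrastDesign` or (n, 5) array.
    """
    Y = _as_response_matrix(table, params.n_items)
    X = _as_design_matrix(design)
    return _loglik_from_stats(params, _pattern_stats(Y, X))


def _as_response_matrix(table, n_items: int | None = None) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        if n_items is None:
            cols = sorted(
                (c for c in table.columns if c.startswith("item_")),
                key=lambda c: int(c.split("_")[1]),
            )
        else:
            cols = [f"item_{j}" for j in range(1, n_items + 1)]
        return table[cols].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def _as_design_matrix(design) -> np.ndarray:
    matrix = getattr(design, "matrix", None)
    if matrix is not None:
        return np.asarray(matrix, dtype=float)
    return np.asarray(design, dtype=float)


# ---------------------------------------------------------------------------
# packing free parameters
# ---------------------------------------------------------------------------


class _Packer:
    """Maps between MNLFAParameters and the packed free-parameter vector.

    Order: nu0 (p), lambda0 (p), log theta (p), beta[active], delta[active],
    kappa[active] (row-major), omega_mod[active].
    """

    def __init__(self, template: MNLFAParameters):
        self.template = template.zero_inactive()
        act = template.active
        self.p = template.n_items
        self.q = template.n_cov
        self.idx_beta = np.flatnonzero(act.beta)
        self.idx_delta = np.flatnonzero(act.delta)
        self.idx_kappa = np.argwhere(act.kappa)
        self.idx_omega = np.argwhere(act.omega_mod)
        self.n_free = 3 * self.p + len(self.idx_beta) + len(self.idx_delta) + len(
            self.idx_kappa
        ) + len(self.idx_omega)

    def names(self) -> list[str]:
        if self.q == 5:
            from .contrasts import COLUMN_NAMES as cov
        else:
            cov = [f"x{k}" for k in range(self.q)]
        out = [f"nu0[{j+1}]" for j in range(self.p)]
        out += [f"lambda0[{j+1}]" for j in range(self.p)]
        out += [f"log_theta[{j+1}]" for j in range(self.p)]
        out += [f"mean~{cov[k]}" for k in self.idx_beta]
        out += [f"variance~{cov[k]}" for k in self.idx_delta]
        out += [f"intercept[{j+1}]~{cov[k]}" for j, k in self.idx_kappa]
        out += [f"loading[{j+1}]~{cov[k]}" for j, k in self.idx_omega]
        return out

    def moderation_slice(self) -> slice:
        return slice(3 * self.p, self.n_free)

    def pack(self, params: MNLFAParameters) -> np.ndarray:
        v = np.empty(self.n_free)
        p = self.p
        v[:p] = params.nu0
        v[p : 2 * p] = params.lambda0
        v[2 * p : 3 * p] = np.log(params.theta)
        pos = 3 * p
        for k in self.idx_beta:
            v[pos] = params.beta[k]
            pos += 1
        for k in self.idx_delta:
            v[pos] = params.delta[k]
            pos += 1
        for j, k in self.idx_kappa:
            v[pos] = params.kappa[j, k]
            pos += 1
        for j, k in self.idx_omega:
            v[pos] = params.omega_mod[j, k]
            pos += 1
        return v

    def unpack(self, v: np.ndarray) -> MNLFAParameters:
        out = self.template.copy()
        p = self.p
        out.nu0 = v[:p].copy()
        out.lambda0 = v[p : 2 * p].copy()
        out.theta = np.exp(np.clip(v[2 * p : 3 * p], -30.0, 30.0))
        pos = 3 * p
        for k in self.idx_beta:
            out.beta[k] = v[pos]
            pos += 1
        for k in self.idx_delta:
            out.delta[k] = v[pos]
            pos += 1
        for j, k in self.idx_kappa:
            out.kappa[j, k] = v[pos]
            pos += 1
        for j, k in self.idx_omega:
            out.omega_mod[j, k] = v[pos]
            pos += 1
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: MNLFAParameters
    loglik: float
    n_obs: int
    converged: bool
    iterations: int
    names: list[str]
    estimates: np.ndarray  # packed vector at optimum
    se: np.ndarray | None  # aligned with names; None if unavailable
    vcov: np.ndarray | None
    grad_norm: float
    moderation_slice: slice

    def parameter_table(self) -> pd.DataFrame:
        se = self.se if self.se is not None else np.full_like(self.estimates, np.nan)
        return pd.DataFrame(
            {"parameter": self.names, "estimate": self.estimates, "se": se}
        )


def fit_mnlfa(
    table,
    design,
    active: ActiveSet | None = None,
    init: MNLFAParameters | None = None,
    tol: float = 1e-6,
    maxiter: int = 500,
    compute_se: bool = True,
) -> FitResult:
    """Maximum-likelihood MNLFA fit.

    ``active`` selects which moderation coefficients are free (defaults to the
    mask carried by ``init``, else none).  Starting values, unless an ``init``
    is given: baseline intercepts at the item means, loadings at 1, uniquenesses
    at half the item variances, moderation at 0.
    """
    Y = _as_response_matrix(table, N_ITEMS if init is None else init.n_items)
    X = _as_design_matrix(design)
    n, p = Y.shape
    q = X.shape[1]
    if init is None:
        init = MNLFAParameters.baseline(
            nu0=Y.mean(axis=0),
            lambda0=np.ones(p),
            theta=np.maximum(Y.var(axis=0) / 2.0, 1e-3),
            n_cov=q,
        )
    else:
        init = init.copy()
    if active is not None:
        init.active = active.copy()
    init = init.zero_inactive()

    packer = _Packer(init)
    if n < packer.n_free:
        raise ValueError(
            f"n = {n} below the number of free parameters ({packer.n_free})"
        )
    stats_list = _pattern_stats(Y, X)

    def negloglik(v: np.ndarray) -> float:
        pr = packer.unpack(v)
        ll = _loglik_from_stats(pr, stats_list)
        if not np.isfinite(ll):
            return 1e12
        return -ll / n

    v0 = packer.pack(init)
    res = optimize.minimize(
        negloglik,
        v0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": tol},
    )
    vhat = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm <= 10 * tol)
    params_hat = packer.unpack(vhat)
    loglik = _loglik_from_stats(params_hat, stats_list)

    se = vcov = None
    if compute_se:
        # Hessian of the per-observation mean negative log-likelihood (O(1) scale,
        # central differences with a relative step; the default step is small
        # enough to let roundoff make the estimate indefinite), rescaled to the
        # observed information.
        eps = 1e-4 * np.maximum(np.abs(vhat), 1.0)
        H = n * numdiff.approx_hess2(vhat, negloglik, epsilon=eps)
        try:
            vcov = np.linalg.inv(H)
            diag = np.diag(vcov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance estimate")
            se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            # near-singular information: fall back to the pseudo-inverse and keep
            # whichever variances come out positive
            vcov = np.linalg.pinv(H)
            diag = np.diag(vcov).copy()
            bad = diag <= 0
            if bad.all():
                warnings.warn(
                    "observed information singular; standard errors unavailable",
                    RuntimeWarning,
                    stacklevel=2,
                )
                se = vcov = None
            else:
                if bad.any():
                    warnings.warn(
                        "observed information near-singular; some standard errors unavailable",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                diag[bad] = np.nan
                se = np.sqrt(diag)

    return FitResult(
        params=params_hat,
        loglik=float(loglik),
        n_obs=n,
        converged=converged,
        iterations=int(res.nit),
        names=packer.names(),
        estimates=vhat.copy(),
        se=se,
        vcov=vcov,
        grad_norm=grad_norm,
        moderation_slice=packer.moderation_slice(),
    )


def wald_tests(fit: FitResult) -> pd.DataFrame:
    """Two-sided normal Wald tests for every active moderation parameter."""
    sl = fit.moderation_slice
    names = fit.names[sl]
    est = fit.estimates[sl]
    if fit.se is None:
        warnings.warn("no standard errors available; Wald report empty", RuntimeWarning)
        return pd.DataFrame(columns=["parameter", "estimate", "se", "z", "p"])
    se = fit.se[sl]
    bad = ~np.isfinite(se)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} moderation parameter(s) without standard errors",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"parameter": names, "estimate": est, "se": se, "z": z, "p": p})
    return out[~bad].reset_index(drop=True)


# ---------------------------------------------------------------------------
# factor scores & reliability
# ---------------------------------------------------------------------------


def posterior_factor_score(params: MNLFAParameters, x: np.ndarray, y: np.ndarray):
    """Posterior (regression-method / EAP) factor score for one person.

    Closed-form normal posterior of eta given y:
    mean = alpha + psi * lam' Sigma^{-1} (y - mu), var = psi - psi^2 lam' Sigma^{-1} lam.
    """
    nu_x, lam, alpha, psi = moderated_item_params(params, x)
    mu = nu_x + lam * alpha
    dinv = 1.0 / params.theta
    a = lam * dinv
    denom = 1.0 + psi * float(lam @ a)
    # lam' Sigma^{-1} v = a'v - (psi * (lam'a)/(denom)) * a'v  => a'v / denom
    resid = np.asarray(y, dtype=float) - mu
    lam_Sinv_resid = float(a @ resid) / denom
    lam_Sinv_lam = float(lam @ a) / denom
    score = alpha + psi * lam_Sinv_resid
    var = psi - psi**2 * lam_Sinv_lam
    return score, var


def posterior_factor_scores(params: MNLFAParameters, table, design) -> np.ndarray:
    """Vectorised posterior-mean scores for a whole table (per covariate pattern)."""
    Y = _as_response_matrix(table, params.n_items)
    X = _as_design_matrix(design)
    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    scores = np.empty(Y.shape[0])
    for g in range(patterns.shape[0]):
        x = patterns[g]
        nu_x, lam, alpha, psi = moderated_item_params(params, x)
        mu = nu_x + lam * alpha
        dinv = 1.0 / params.theta
        a = lam * dinv
        denom = 1.0 + psi * float(lam @ a)
        idx = inverse == g
        resid = Y[idx] - mu
        scores[idx] = alpha + psi * (resid @ a) / denom
    return scores


def coefficient_omega(params: MNLFAParameters) -> float:
    """Model-based reliability (coefficient omega) at the baseline x = 0.

    omega = (sum lambda)^2 * psi0 / ((sum lambda)^2 * psi0 + sum theta), psi0 = 1.
    """
    s = float(params.lambda0.sum())
    num = s * s  # psi0 = 1 at baseline
    return num / (num + float(params.theta.sum()))
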