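"""Stage-1 multiple-group confirmatory factor analysis (configural/metric/scalar).

A unidimensional normal-theory CFA is fitted jointly to the six intersectional
cells under three incrementally constrained levels of measurement equivalence:

* **configural** — same one-factor structure in every group, all loadings,
  intercepts and uniquenesses group-specific; identified by fixing each group's
  factor mean at 0 and variance at 1;
* **metric** — loadings equated across groups; factor variances free in all but
  the first (reference) group;
* **scalar** — loadings and intercepts equated; factor means and variances free
  in all but the reference group.

Estimation is plain maximum likelihood on per-group sufficient statistics; fit is
summarised by the ML chi-square against the saturated model, CFI against an
independence baseline (free means and variances, zero covariances per group), and
RMSEA with a 90% CI obtained by inverting the noncentral chi-square distribution.
The multi-group RMSEA uses total n by default; the sqrt(G) convention is available
behind a switch.  Robust (scaled) statistics are not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mnlfa import _PatternStats, _as_response_matrix, _pattern_loglik

__all__ = [
    "LEVELS",
    "MGCFAFit",
    "CFAFitIndices",
    "group_labels",
    "fit_mgcfa",
    "fit_indices",
    "nested_comparison",
]

LEVELS = ("configural", "metric", "scalar")
_LOG2PI = float(np.log(2.0 * np.pi))


def group_labels(table: pd.DataFrame) -> pd.Series:
    """Six-cell intersectional labels like ``'Black female'``."""
    return table["race_ethnicity"].astype(str) + " " + table["sex"].astype(str)


@dataclass
class _GroupStats:
    name: str
    n: int
    ybar: np.ndarray
    S: np.ndarray  # MLE covariance (divisor n)

    @property
    def loglik_saturated(self) -> float:
        p = self.ybar.shape[0]
        sign, logdet = np.linalg.slogdet(self.S)
        return -0.5 * self.n * (p * _LOG2PI + logdet + p)

    @property
    def loglik_independence(self) -> float:
        p = self.ybar.shape[0]
        return -0.5 * self.n * (p * _LOG2PI + float(np.log(np.diag(self.S)).sum()) + p)


def _group_stats(Y: np.ndarray, labels: np.ndarray) -> list[_GroupStats]:
    out = []
    for name in pd.unique(labels):
        Yg = Y[labels == name]
        n = Yg.shape[0]
        ybar = Yg.mean(axis=0)
        D = Yg - ybar
        out.append(_GroupStats(name=str(name), n=n, ybar=ybar, S=(D.T @ D) / n))
    return out


@dataclass
class MGCFAFit:
    level: str
    group_names: list[str]
    n_per_group: dict[str, int]
    params: dict[str, dict[str, np.ndarray | float]]  # per group: nu, lam, theta, alpha, psi
    loglik: float
    loglik_saturated: float
    loglik_independence: float
    n_free: int
    df: int
    df_baseline: int
    converged: bool
    iterations: int

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())

    @property
    def chi2(self) -> float:
        return max(2.0 * (self.loglik_saturated - self.loglik), 0.0)

    @property
    def chi2_baseline(self) -> float:
        return max(2.0 * (self.loglik_saturated - self.loglik_independence), 0.0)


@dataclass
class CFAFitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    note: str = ""


# --- parameter packing per invariance level -------------------------------


class _MGPacker:
    def __init__(self, level: str, G: int, p: int):
        if level not in LEVELS:
            raise ValueError(f"unknown invariance level {level!r}")
        self.level, self.G, self.p = level, G, p
        if level == "configural":
            self.n_free = G * 3 * p
        elif level == "metric":
            self.n_free = p + G * 2 * p + (G - 1)
        else:  # scalar
            self.n_free = p + p + G * p + 2 * (G - 1)

    def unpack(self, v: np.ndarray) -> list[dict]:
        G, p = self.G, self.p
        out = []
        if self.level == "configural":
            for g in range(G):
                o = g * 3 * p
                out.append(
                    dict(
                        nu=v[o : o + p],
                        lam=v[o + p : o + 2 * p],
                        theta=np.exp(np.clip(v[o + 2 * p : o + 3 * p], -30, 30)),
                        alpha=0.0,
                        psi=1.0,
                    )
                )
        elif self.level == "metric":
            lam = v[:p]
            pos = p
            for g in range(G):
                nu = v[pos : pos + p]
                theta = np.exp(np.clip(v[pos + p : pos + 2 * p], -30, 30))
                pos += 2 * p
                out.append(dict(nu=nu, lam=lam, theta=theta, alpha=0.0, psi=1.0))
            for g in range(1, G):
                out[g]["psi"] = float(np.exp(np.clip(v[pos], -30, 30)))
                pos += 1
        else:  # scalar
            lam = v[:p]
            nu = v[p : 2 * p]
            pos = 2 * p
            for g in range(G):
                theta = np.exp(np.clip(v[pos : pos + p], -30, 30))
                pos += p
                out.append(dict(nu=nu, lam=lam, theta=theta, alpha=0.0, psi=1.0))
            for g in range(1, G):
                out[g]["psi"] = float(np.exp(np.clip(v[pos], -30, 30)))
                out[g]["alpha"] = float(v[pos + 1])
                pos += 2
        return out


def _model_loglik(groups: list[dict], stats_list: list[_GroupStats]) -> float:
    total = 0.0
    for prm, st in zip(groups, stats_list):
        lam = np.asarray(prm["lam"], dtype=float)
        mu = np.asarray(prm["nu"], dtype=float) + lam * prm["alpha"]
        ps = _PatternStats(x=np.empty(0), n=st.n, ybar=st.ybar, S=st.S)
        total += _pattern_loglik(mu, lam, prm["psi"], np.asarray(prm["theta"]), ps)
    return total


def fit_mgcfa(
    table: pd.DataFrame,
    groups: pd.Series | np.ndarray | None = None,
    level: str = "configural",
    maxiter: int = 1000,
) -> MGCFAFit:
    """Fit the multi-group one-factor model at the requested invariance level."""
    Y = _as_response_matrix(table)
    p = Y.shape[1]
    if groups is None:
        groups = group_labels(table)
    labels = np.asarray(groups)
    stats_list = _group_stats(Y, labels)
    G = len(stats_list)
    if G < 2:
        raise ValueError("multiple-group CFA requires at least 2 groups")
    per_group_free = 3 * p  # worst case (configural)
    for st in stats_list:
        if st.n <= per_group_free:
            raise ValueError(
                f"group {st.name!r} has n = {st.n} <= {per_group_free} within-group free parameters"
            )

    packer = _MGPacker(level, G, p)

    # starting values: per-group item means, loadings from first PC scaled, theta/2
    v0 = _start_values(packer, stats_list)

    n_total = sum(st.n for st in stats_list)

    def nll(v: np.ndarray) -> float:
        ll = _model_loglik(packer.unpack(v), stats_list)
        if not np.isfinite(ll):
            return 1e12
        return -ll / n_total

    res = optimize.minimize(
        nll, v0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7}
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm <= 1e-5)
    group_params = packer.unpack(res.x)
    loglik = _model_loglik(group_params, stats_list)

    n_moments = G * (p + p * (p + 1) // 2)
    return MGCFAFit(
        level=level,
        group_names=[st.name for st in stats_list],
        n_per_group={st.name: st.n for st in stats_list},
        params={st.name: prm for st, prm in zip(stats_list, group_params)},
        loglik=float(loglik),
        loglik_saturated=float(sum(st.loglik_saturated for st in stats_list)),
        loglik_independence=float(sum(st.loglik_independence for st in stats_list)),
        n_free=packer.n_free,
        df=n_moments - packer.n_free,
        df_baseline=n_moments - G * 2 * p,
        converged=converged,
        iterations=int(res.nit),
    )


def _start_values(packer: _MGPacker, stats_list: list[_GroupStats]) -> np.ndarray:
    G, p = packer.G, packer.p
    lam0, nu0, logth0 = [], [], []
    for st in stats_list:
        # first principal axis of S as a loading start, sign-aligned positive
        w, V = np.linalg.eigh(st.S)
        lam = V[:, -1] * np.sqrt(max(w[-1], 1e-6))
        if lam.sum() < 0:
            lam = -lam
        lam0.append(lam)
        nu0.append(st.ybar)
        logth0.append(np.log(np.maximum(np.diag(st.S) - lam**2, np.diag(st.S) / 4)))
    if packer.level == "configural":
        return np.concatenate([np.concatenate([nu0[g], lam0[g], logth0[g]]) for g in range(G)])
    lam_bar = np.mean(lam0, axis=0)
    if packer.level == "metric":
        parts = [lam_bar]
        for g in range(G):
            parts += [nu0[g], logth0[g]]
        parts.append(np.zeros(G - 1))  # log psi
        return np.concatenate(parts)
    # scalar
    nu_bar = np.mean(nu0, axis=0)
    parts = [lam_bar, nu_bar]
    for g in range(G):
        parts.append(logth0[g])
    parts.append(np.zeros(2 * (G - 1)))  # log psi, alpha interleaved per group
    return np.concatenate(parts)


def fit_indices(fit: MGCFAFit, sqrt_g: bool = False) -> CFAFitIndices:
    """ML chi-square, CFI and RMSEA (90% CI by noncentral-chi2 inversion)."""
    chi2 = fit.chi2
    df = fit.df
    note = ""
    p_val = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    chi2_b, df_b = fit.chi2_baseline, fit.df_baseline
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    n = fit.n_total
    if df == 0:
        note = "df = 0: RMSEA undefined, reported as 0"
        rmsea, ci = 0.0, (0.0, 0.0)
    else:
        scale = np.sqrt(len(fit.group_names)) if sqrt_g else 1.0
        rmsea = scale * float(np.sqrt(num / (df * n)))
        ci = tuple(
            scale * b for b in _rmsea_ci(chi2, df, n, level=0.90)
        )
    return CFAFitIndices(
        chi2=chi2, df=df, p=p_val, cfi=float(np.clip(cfi, 0.0, 1.0)), rmsea=rmsea,
        rmsea_ci90=ci, note=note,
    )


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square CDF for the RMSEA confidence bounds."""
    lo_q = 0.5 + level / 2.0  # 0.95
    hi_q = 0.5 - level / 2.0  # 0.05

    def nc_for(q: float) -> float:
        # find nc >= 0 with ncx2.cdf(chi2, df, nc) = q; cdf decreases in nc
        if stats.ncx2.cdf(chi2, df, 1e-10) <= q:
            return 0.0
        hi = max(chi2 - df, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > q:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return float(optimize.brentq(lambda nc: stats.ncx2.cdf(chi2, df, nc) - q, 1e-10, hi, xtol=1e-10))

    lo = nc_for(lo_q)
    hi = nc_for(hi_q)
    return (float(np.sqrt(lo / (df * n))), float(np.sqrt(hi / (df * n))))


def nested_comparison(fit_less: MGCFAFit, fit_more: MGCFAFit, sqrt_g: bool = False) -> dict:
    """Compare nested invariance levels with the three decision criteria.

    ``fit_less`` is the less restricted model (e.g. configural), ``fit_more`` the
    more restricted (e.g. metric).  Decision is "decrement" if any criterion
    fires: delta-CFI > 0.01, chi-square difference p < .05, or disjoint RMSEA
    90% CIs.
    """
    order = {lv: i for i, lv in enumerate(LEVELS)}
    if order[fit_more.level] <= order[fit_less.level]:
        raise ValueError(
            f"models not nested in the expected direction: {fit_less.level} vs {fit_more.level}"
        )
    if fit_less.n_per_group != fit_more.n_per_group:
        raise ValueError("nested comparison requires fits on the same data")
    delta_chi2 = max(fit_more.chi2 - fit_less.chi2, 0.0)
    delta_df = fit_more.df - fit_less.df
    p = float(stats.chi2.sf(delta_chi2, delta_df))
    ix_less = fit_indices(fit_less, sqrt_g=sqrt_g)
    ix_more = fit_indices(fit_more, sqrt_g=sqrt_g)
    delta_cfi = ix_less.cfi - ix_more.cfi
    lo1, hi1 = ix_less.rmsea_ci90
    lo2, hi2 = ix_more.rmsea_ci90
    overlap = not (hi1 < lo2 or hi2 < lo1)
    decrement = (delta_cfi > 0.01) or (p < 0.05) or (not overlap)
    return {
        "delta_chi2": delta_chi2,
        "delta_df": delta_df,
        "p": p,
        "delta_cfi": delta_cfi,
        "rmsea_ci_overlap": overlap,
        "decision": "decrement" if decrement else "no decrement",
    }


def comparison_table(fits: dict[str, MGCFAFit]) -> pd.DataFrame:
    """Configural/metric/scalar fit-index summary table."""
    rows = []
    for level in LEVELS:
        if level not in fits:
            continue
        ix = fit_indices(fits[level])
        rows.append(
            {
                "level": level,
                "chi2": ix.chi2,
                "df": ix.df,
                "p": ix.p,
                "cfi": ix.cfi,
                "rmsea": ix.rmsea,
                "rmsea_lo90": ix.rmsea_ci90[0],
                "rmsea_hi90": ix.rmsea_ci90[1],
            }
        )
    return pd.DataFrame(rows)
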