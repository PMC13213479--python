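"""Synthetic person-level item-response tables with the structure the analysis assumes.

The generator emulates a cohort answering a 7-item perceived-discrimination scale on
a 5-point Likert scale ((1) "Almost never" ... (5) "Very often"): six intersectional
cells (Black/Latinx/White x female/male) at the study composition (15.90% Black,
22.42% Latinx, 61.68% White; 47.53% female; n = 9,360), a unidimensional latent
factor whose mean may differ across cells, heavily right-skewed responses (category
1 modal for every item), and injectable intercept DIF by sex on items 1 and 3.

Responses are generated from the linear-normal MNLFA (see :mod:`pdsmeq.mnlfa`) on a
continuous latent response scale and then discretised by fixed per-item thresholds;
DIF is injected on the continuous scale, matching the model the pipeline fits.  A
continuous-output flag skips discretisation, which is the regime in which the fitted
model class coincides exactly with the generating process.

Baseline parameters (loadings, uniquenesses, thresholds) are package constants with
no claim of being estimates from any real dataset; they were calibrated once so that
closed-form coefficient omega is 0.66 (within the 0.60-0.72 window) and the Likert
output is right-skewed with cell mean scores in the 1.05-1.35 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import GroupLabel, all_groups, build_contrast_codes
from .mnlfa import ActiveSet, MNLFAParameters, N_COVARIATES, N_ITEMS

__all__ = [
    "STUDY_N",
    "GROUP_COUNTS",
    "DEFAULT_PROPORTIONS",
    "DEFAULT_NU0",
    "DEFAULT_LAMBDA0",
    "DEFAULT_THETA",
    "DEFAULT_THRESHOLDS",
    "KAPPA_ITEM1_SEX",
    "KAPPA_ITEM3_SEX",
    "BETA_RACE1",
    "BETA_RACE2",
    "GeneratorConfig",
    "default_true_params",
    "simulate_dataset",
    "simulate_weights",
    "discretize",
]

#: Analytic sample size of the study being emulated.
STUDY_N = 9360

#: Cell counts (female/male x Black/Latinx/White) reproducing the printed
#: composition: 47.53% female, 15.90% Black, 22.42% Latinx, 61.68% White.
GROUP_COUNTS: dict[tuple[str, str], int] = {
    ("female", "Black"): 747,
    ("male", "Black"): 741,
    ("female", "Latinx"): 1007,
    ("male", "Latinx"): 1092,
    ("female", "White"): 2695,
    ("male", "White"): 3078,
}

DEFAULT_PROPORTIONS: dict[tuple[str, str], float] = {
    k: v / STUDY_N for k, v in GROUP_COUNTS.items()
}

# --- package baseline measurement parameters (calibrated constants, no data
# provenance).  Closed-form omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta)
# = 0.66 at these values.
DEFAULT_NU0 = np.zeros(N_ITEMS)
DEFAULT_LAMBDA0 = np.array([0.60, 0.55, 0.60, 0.55, 0.50, 0.50, 0.55])
DEFAULT_THETA = np.array([1.15, 1.05, 1.15, 1.10, 1.00, 1.00, 1.18])
# per-item Likert cut-points on the latent response scale (ascending)
DEFAULT_THRESHOLDS = np.tile(np.array([1.05, 2.10, 3.20, 4.30]), (N_ITEMS, 1))

#: True sex-moderation of the item-1 and item-3 intercepts in the final-model
#: scenario (the two DIF effects the pipeline is expected to find).
KAPPA_ITEM1_SEX = -0.21
KAPPA_ITEM3_SEX = -0.15

#: Race/ethnicity effects on the latent factor mean in the final-model scenario,
#: calibrated once so the adjusted-score group gaps are of the magnitude the
#: analysis reports (Hedges' g of 0.851 Black-White and 0.515 Latinx-White).
#: Under the baseline measurement parameters the posterior factor scores have
#: within-group SD sqrt(1 - 1/(1 + sum lambda_j^2/theta_j)) = 0.813, so the
#: latent mean gaps are g x 0.813 (B-W = 0.692, L-W = 0.419); with the Helmert
#: codes alpha = beta1*race1 + beta2*race2, B-W = -beta1 - beta2/2 and
#: L-W = -beta1 + beta2/2, giving:
BETA_RACE1 = -0.5551
BETA_RACE2 = -0.2731


def default_true_params(scenario: str = "null") -> MNLFAParameters:
    """Generating parameters for a named scenario.

    ``"null"``: fully invariant, no structural or measurement moderation.
    ``"final_model"``: sex intercept DIF of -0.21 on item 1 and -0.15 on item 3,
    race effects on the factor mean (``BETA_RACE1``, ``BETA_RACE2``), everything
    else invariant.
    """
    params = MNLFAParameters.baseline(
        nu0=DEFAULT_NU0.copy(),
        lambda0=DEFAULT_LAMBDA0.copy(),
        theta=DEFAULT_THETA.copy(),
    )
    if scenario == "null":
        return params
    if scenario == "final_model":
        params.kappa[0, 0] = KAPPA_ITEM1_SEX  # item 1 x sex
        params.kappa[2, 0] = KAPPA_ITEM3_SEX  # item 3 x sex
        params.beta[1] = BETA_RACE1  # race1
        params.beta[2] = BETA_RACE2  # race2
        act = ActiveSet.none()
        act.kappa[0, 0] = act.kappa[2, 0] = True
        act.beta[1] = act.beta[2] = True
        params.active = act
        return params
    raise ValueError(f"unknown scenario {scenario!r} (expected 'null' or 'final_model')")


@dataclass
class GeneratorConfig:
    """Settings for one simulated cohort."""

    n: int = STUDY_N
    group_proportions: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    true_params: MNLFAParameters = field(default_factory=lambda: default_true_params("null"))
    thresholds: np.ndarray = field(default_factory=lambda: DEFAULT_THRESHOLDS.copy())
    weight_model: tuple | None = None  # e.g. ("lognormal", 0.3) or ("constant",)
    seed: int = 0
    continuous: bool = False  # emit pre-discretisation responses instead of Likert
    missing_rate: float = 0.0  # optional MCAR missingness on items

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        probs = np.array(list(self.group_proportions.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("group proportions must be nonnegative and sum to 1")
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.shape != (N_ITEMS, 4):
            raise ValueError(f"thresholds must be {N_ITEMS} x 4")
        if np.any(np.diff(thr, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def discretize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map continuous item values to Likert 1-5 by ascending cut-points.

    ``value <= t1 -> 1``, ``(t1, t2] -> 2``, ..., ``> t4 -> 5``; monotone in the
    latent value.  ``latent`` is (n, p) and ``thresholds`` (p, 4).
    """
    latent = np.asarray(latent, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds, axis=1) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    out = np.empty(latent.shape, dtype=np.int64)
    for j in range(latent.shape[-1]):
        # side='left': values equal to a cut-point fall in the lower category
        out[..., j] = 1 + np.searchsorted(thresholds[j], latent[..., j], side="left")
    return out


def simulate_weights(n: int, weight_model: tuple | None, seed: int) -> np.ndarray:
    """Positive sampling weights with mean approximately 1, deterministic given seed."""
    if weight_model is None or weight_model[0] == "constant":
        return np.ones(n)
    kind = weight_model[0]
    if kind == "lognormal":
        sigma = float(weight_model[1]) if len(weight_model) > 1 else 0.3
        if sigma <= 0:
            raise ValueError("lognormal sigma must be positive")
        rng = np.random.default_rng(seed)
        # mean-1 lognormal: E[exp(N(mu, sigma^2))] = exp(mu + sigma^2/2) = 1
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    raise ValueError(f"unsupported weight model {weight_model!r}")


def simulate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one cohort: labels, latent factor, continuous responses, Likert items.

    Deterministic given ``config.seed``.  With ``config.continuous`` the item
    columns hold the pre-discretisation continuous responses (floats).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = list(config.group_proportions.keys())
    probs = np.array([config.group_proportions[c] for c in cells])
    cell_idx = rng.choice(len(cells), size=config.n, p=probs)

    codes = np.array(
        [[float(v) for v in build_contrast_codes(GroupLabel(*c))] for c in cells]
    )
    X = codes[cell_idx]  # (n, 5)

    pr = config.true_params
    alpha = X @ pr.beta
    psi = np.exp(X @ pr.delta)
    eta = alpha + np.sqrt(psi) * rng.standard_normal(config.n)

    nu = pr.nu0 + X @ pr.kappa.T  # (n, 7)
    lam = pr.lambda0 + X @ pr.omega_mod.T
    noise = rng.standard_normal((config.n, pr.n_items)) * np.sqrt(pr.theta)
    ystar = nu + lam * eta[:, None] + noise

    if config.continuous:
        items = ystar
    else:
        items = discretize(ystar, config.thresholds)

    weights = simulate_weights(
        config.n, config.weight_model, seed=int(rng.integers(2**31 - 1))
    )

    table = pd.DataFrame(
        {
            "person_id": np.arange(1, config.n + 1),
            **{f"item_{j+1}": items[:, j] for j in range(pr.n_items)},
            "sex": [cells[i][0] for i in cell_idx],
            "race_ethnicity": [cells[i][1] for i in cell_idx],
            "weight": weights,
        }
    )
    if config.missing_rate > 0:
        mask = rng.random((config.n, pr.n_items)) < config.missing_rate
        item_cols = [f"item_{j+1}" for j in range(pr.n_items)]
        vals = table[item_cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        table[item_cols] = vals
    return table
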