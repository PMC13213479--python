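"""Staged MNLFA model building: impact screen, item DIF screen, conditional model,
FDR trimming, final model.

The workflow mirrors the semi-automated scale-scoring procedure used with
moderated nonlinear factor analysis:

1. **Impact step** — all five contrast-coded covariates moderate the factor mean
   and (log-)variance with a fully invariant measurement model; retention units
   containing any effect with p < .10 are carried forward.
2. **Item DIF step** — for each item in turn, all five covariates moderate that
   item's intercept and loading (other items invariant, carried impact effects
   included); units with any member at p <= .05 are carried forward.
3. **Conditional model** — one simultaneous fit of every carried effect.
   Structural (mean/variance) units are kept for the final model only if
   significant at p < .05 in this model; measurement units pass to trimming.
4. **FDR trimming** — Benjamini–Hochberg at q = .05 applied first to loading
   units, refit, then to intercept units, refit.  The BH family is the complete
   set of tested units of that class (21 item x covariate-unit combinations;
   units screened out earlier enter with p = 1), and each unit's p-value is the
   Šidák-corrected minimum of its member p-values, a valid union test for "any
   member nonzero".  The surviving model is the scoring model.

Race/ethnicity contrast codes (and the two interaction codes) are retained as
pairs throughout: a unit is significant when any member crosses the threshold,
and trimming keeps or drops whole units by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .contrasts import COLUMN_NAMES
from .mnlfa import (
    ActiveSet,
    FitResult,
    MNLFAParameters,
    N_COVARIATES,
    N_ITEMS,
    fit_mnlfa,
    wald_tests,
)

__all__ = [
    "EffectKey",
    "SelectionConfig",
    "PipelineResult",
    "pair_groups",
    "impact_step",
    "item_dif_step",
    "conditional_step",
    "bh_fdr",
    "fdr_trim",
    "run_pipeline",
]

Target = Literal["mean", "variance", "intercept", "loading"]


@dataclass(frozen=True, order=True)
class EffectKey:
    """One moderation parameter: a target (optionally item-specific) x covariate."""

    target: Target
    item: int | None  # 1-based item index for intercept/loading, None for structural
    covariate: str  # one of the 5 contrast-code column names

    def __post_init__(self) -> None:
        if self.target in ("mean", "variance"):
            if self.item is not None:
                raise ValueError("structural effects carry no item index")
        else:
            if self.item is None or not 1 <= self.item <= N_ITEMS:
                raise ValueError(f"item index must be in 1..{N_ITEMS}")
        if self.covariate not in COLUMN_NAMES:
            raise ValueError(f"unknown covariate {self.covariate!r}")

    def __str__(self) -> str:
        if self.item is None:
            return f"{self.target}~{self.covariate}"
        return f"{self.target}[{self.item}]~{self.covariate}"


def pair_groups() -> dict[str, tuple[str, ...]]:
    """Retention units: sex alone; the race pair; the interaction pair."""
    return {
        "sex": ("sex",),
        "race": ("race1", "race2"),
        "sex_race": ("sex_race1", "sex_race2"),
    }


_UNIT_OF_COV = {cov: unit for unit, covs in pair_groups().items() for cov in covs}


@dataclass(frozen=True, order=True)
class UnitKey:
    """A retention unit: a (target, item) paired with a covariate unit."""

    target: Target
    item: int | None
    unit: str  # "sex" | "race" | "sex_race"

    def members(self) -> list[EffectKey]:
        return [EffectKey(self.target, self.item, c) for c in pair_groups()[self.unit]]

    def __str__(self) -> str:
        if self.item is None:
            return f"{self.target}~{self.unit}"
        return f"{self.target}[{self.item}]~{self.unit}"


def _unit_of(effect: EffectKey) -> UnitKey:
    return UnitKey(effect.target, effect.item, _UNIT_OF_COV[effect.covariate])


def all_units(target: Target) -> list[UnitKey]:
    """Every tested retention unit of one class (the BH family for trimming)."""
    units = list(pair_groups())
    if target in ("mean", "variance"):
        return [UnitKey(target, None, u) for u in units]
    return [UnitKey(target, j, u) for j in range(1, N_ITEMS + 1) for u in units]


@dataclass
class SelectionConfig:
    """Thresholds and modes of the staged selection (defaults follow the procedure
    described above: .10 impact screen — strict; .05 item screen — inclusive;
    .05 conditional re-screen — strict; BH q = .05)."""

    impact_threshold: float = 0.10
    item_threshold: float = 0.05
    conditional_threshold: float = 0.05
    fdr_q: float = 0.05
    trim_by_unit: bool = True  # BH over units (Šidák min-p) vs individual parameters
    trim_family: Literal["all_tested", "carried"] = "all_tested"
    fit_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("impact_threshold", "item_threshold", "conditional_threshold", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_COV_INDEX = {c: k for k, c in enumerate(COLUMN_NAMES)}


def _activate(effects: Iterable[EffectKey]) -> ActiveSet:
    act = ActiveSet.none()
    for e in effects:
        k = _COV_INDEX[e.covariate]
        if e.target == "mean":
            act.beta[k] = True
        elif e.target == "variance":
            act.delta[k] = True
        elif e.target == "intercept":
            act.kappa[e.item - 1, k] = True
        else:
            act.omega_mod[e.item - 1, k] = True
    return act


def _effect_name(e: EffectKey) -> str:
    # parameter naming used by the fitter's packed vector
    if e.target == "mean":
        return f"mean~{e.covariate}"
    if e.target == "variance":
        return f"variance~{e.covariate}"
    return f"{e.target}[{e.item}]~{e.covariate}"


def _pvalues(fit: FitResult, effects: Sequence[EffectKey]) -> dict[EffectKey, tuple[float, float, float]]:
    """Map each effect to (estimate, se, p) from the fit's Wald report."""
    rep = wald_tests(fit).set_index("parameter")
    out = {}
    for e in effects:
        row = rep.loc[_effect_name(e)]
        out[e] = (float(row["estimate"]), float(row["se"]), float(row["p"]))
    return out


def _sidak(min_p: float, k: int) -> float:
    """Union-test p-value from the minimum of k member p-values."""
    return float(1.0 - (1.0 - min_p) ** k)


def _unit_pvalue(unit: UnitKey, pvals: dict[EffectKey, tuple[float, float, float]]) -> float:
    members = unit.members()
    mp = min(pvals[m][2] for m in members)
    return _sidak(mp, len(members))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def impact_step(table, design, config: SelectionConfig | None = None, trace: list | None = None):
    """Screen factor-mean and factor-variance moderation (all covariates, invariant
    measurement); retain units with any member p < threshold (strict)."""
    config = config or SelectionConfig()
    effects = [EffectKey(t, None, c) for t in ("mean", "variance") for c in COLUMN_NAMES]
    fit = fit_mnlfa(table, design, active=_activate(effects), **config.fit_kwargs)
    if not fit.converged:
        raise RuntimeError("impact model did not converge")
    pvals = _pvalues(fit, effects)
    retained: list[UnitKey] = []
    for unit in all_units("mean") + all_units("variance"):
        mem = unit.members()
        min_p = min(pvals[m][2] for m in mem)
        keep = min_p < config.impact_threshold
        if keep:
            retained.append(unit)
        if trace is not None:
            for m in mem:
                est, se, p = pvals[m]
                trace.append(
                    _trace_record("impact", m, est, se, p, config.impact_threshold, keep,
                                  "own p" if p < config.impact_threshold else
                                  ("paired partner" if keep else "screened out"))
                )
    return retained, fit


def item_dif_step(table, design, impact_units: Sequence[UnitKey],
                  config: SelectionConfig | None = None, trace: list | None = None):
    """Per-item DIF screen: free all covariates on one item's intercept and loading
    (carried impact effects included); retain units with any member p <= threshold."""
    config = config or SelectionConfig()
    impact_effects = [m for u in impact_units for m in u.members()]
    retained: list[UnitKey] = []
    screen_pvalues: dict[UnitKey, float] = {}
    for j in range(1, N_ITEMS + 1):
        effects = [EffectKey(t, j, c) for t in ("intercept", "loading") for c in COLUMN_NAMES]
        try:
            fit = fit_mnlfa(table, design, active=_activate(impact_effects + effects),
                            **config.fit_kwargs)
            if not fit.converged:
                raise RuntimeError("non-convergence")
            pvals = _pvalues(fit, effects)
        except Exception as err:  # pragma: no cover - defensive per-item skip
            import warnings

            warnings.warn(f"item {j} DIF screen skipped: {err}", RuntimeWarning)
            continue
        for target in ("intercept", "loading"):
            for unit_name in pair_groups():
                unit = UnitKey(target, j, unit_name)
                mem = unit.members()
                min_p = min(pvals[m][2] for m in mem)
                screen_pvalues[unit] = min_p
                keep = min_p <= config.item_threshold
                if keep:
                    retained.append(unit)
                if trace is not None:
                    for m in mem:
                        est, se, p = pvals[m]
                        trace.append(
                            _trace_record(f"item_{j}", m, est, se, p, config.item_threshold,
                                          keep, "own p" if p <= config.item_threshold else
                                          ("paired partner" if keep else "screened out"))
                        )
    return retained, screen_pvalues


def _anchor_for_identification(carried: Sequence[UnitKey],
                               screen_pvalues: dict[UnitKey, float] | None,
                               trace: list | None) -> list[UnitKey]:
    """Restore identification when a factor-mean unit and the matching intercept
    unit of *every* item are carried simultaneously.

    A common intercept shift across all items is exactly collinear with a factor-
    mean shift (add c to beta_k, subtract lambda_j c from every kappa_jk), so the
    simultaneous model would sit on a likelihood ridge.  The item with the weakest
    screening evidence (largest screen p) is anchored: its intercept unit for that
    covariate unit is removed, making the remaining DIF effects interpretable as
    deviations from the anchor item.
    """
    carried = list(carried)
    for unit_name in pair_groups():
        mean_unit = UnitKey("mean", None, unit_name)
        item_units = [u for u in carried if u.target == "intercept" and u.unit == unit_name]
        if mean_unit in carried and len(item_units) == N_ITEMS:
            if screen_pvalues:
                anchor = max(item_units, key=lambda u: screen_pvalues.get(u, 0.0))
            else:
                anchor = max(item_units, key=lambda u: u.item)
            carried.remove(anchor)
            if trace is not None:
                for m in anchor.members():
                    trace.append(
                        _trace_record("conditional", m, np.nan, np.nan, np.nan,
                                      np.nan, False, "anchor item (identification)"))
    return carried


def conditional_step(table, design, carried: Sequence[UnitKey],
                     config: SelectionConfig | None = None, trace: list | None = None,
                     screen_pvalues: dict[UnitKey, float] | None = None):
    """Simultaneous fit of every carried effect; structural units must re-qualify at
    p < threshold to enter the final model, measurement units pass to trimming."""
    config = config or SelectionConfig()
    carried = _anchor_for_identification(carried, screen_pvalues, trace)
    effects = [m for u in carried for m in u.members()]
    fit = fit_mnlfa(table, design, active=_activate(effects), **config.fit_kwargs)
    if not fit.converged:
        raise RuntimeError(
            "conditional model did not converge; carried effects: "
            + ", ".join(str(u) for u in carried)
        )
    pvals = _pvalues(fit, effects) if effects else {}
    structural_final: list[UnitKey] = []
    measurement: list[UnitKey] = []
    for unit in carried:
        mem = unit.members()
        min_p = min(pvals[m][2] for m in mem)
        if unit.target in ("mean", "variance"):
            keep = min_p < config.conditional_threshold
            if keep:
                structural_final.append(unit)
            reason_kept = "own p"
        else:
            keep = True  # measurement: decided by FDR trimming
            measurement.append(unit)
            reason_kept = "to FDR trimming"
        if trace is not None:
            for m in mem:
                est, se, p = pvals[m]
                trace.append(
                    _trace_record("conditional", m, est, se, p,
                                  config.conditional_threshold, keep,
                                  reason_kept if keep else "conditional re-screen"))
    return structural_final, measurement, fit


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def fdr_trim(table, design, structural: Sequence[UnitKey], measurement: Sequence[UnitKey],
             conditional_fit: FitResult, config: SelectionConfig | None = None,
             trace: list | None = None):
    """Sequential BH trimming of measurement units: loadings first, then intercepts,
    refitting after each pass.  Returns (final_fit, final_units)."""
    config = config or SelectionConfig()
    loading_units = [u for u in measurement if u.target == "loading"]
    intercept_units = [u for u in measurement if u.target == "intercept"]

    current_fit = conditional_fit
    survivors_load = _trim_pass("loading", loading_units, current_fit, config, trace)

    structural = list(structural)
    active_units = structural + survivors_load + intercept_units
    refit = _refit(table, design, active_units, config, current_fit)

    survivors_int = _trim_pass("intercept", intercept_units, refit, config, trace)

    final_units = structural + survivors_load + survivors_int
    final_fit = _refit(table, design, final_units, config, refit)
    return final_fit, final_units


def _trim_pass(target: Target, units: list[UnitKey], fit: FitResult,
               config: SelectionConfig, trace: list | None) -> list[UnitKey]:
    if not units:
        return []
    effects = [m for u in units for m in u.members()]
    pvals = _pvalues(fit, effects)
    if config.trim_by_unit:
        family = all_units(target) if config.trim_family == "all_tested" else units
        unit_p = {u: (_unit_pvalue(u, pvals) if u in units else 1.0) for u in family}
        ordered = list(family)
        reject = bh_fdr([unit_p[u] for u in ordered], q=config.fdr_q)
        kept_set = {u for u, r in zip(ordered, reject) if r and u in units}
    else:
        # per-parameter BH over the full family of individual effects
        if config.trim_family == "all_tested":
            fam_effects = [m for u in all_units(target) for m in u.members()]
        else:
            fam_effects = effects
        pv = [pvals[e][2] if e in pvals else 1.0 for e in fam_effects]
        reject = bh_fdr(pv, q=config.fdr_q)
        rejected_effects = {e for e, r in zip(fam_effects, reject) if r}
        kept_set = {u for u in units if any(m in rejected_effects for m in u.members())}
    if trace is not None:
        for u in units:
            keep = u in kept_set
            for m in u.members():
                est, se, p = pvals[m]
                trace.append(
                    _trace_record(f"fdr_trim_{target}", m, est, se, p, config.fdr_q,
                                  keep, "BH retained" if keep else "FDR trim"))
    return [u for u in units if u in kept_set]


def _refit(table, design, units: Sequence[UnitKey], config: SelectionConfig,
           last_fit: FitResult) -> FitResult:
    effects = [m for u in units for m in u.members()]
    # skip the refit when the active set is unchanged
    act = _activate(effects)
    prev = last_fit.params.active
    if (np.array_equal(act.beta, prev.beta) and np.array_equal(act.delta, prev.delta)
            and np.array_equal(act.kappa, prev.kappa)
            and np.array_equal(act.omega_mod, prev.omega_mod)):
        return last_fit
    try:
        fit = fit_mnlfa(table, design, active=_activate(effects),
                        init=last_fit.params, **config.fit_kwargs)
        if not fit.converged:
            raise RuntimeError("refit non-convergence")
        return fit
    except Exception:
        import warnings

        warnings.warn("trim refit failed; returning last converged model", RuntimeWarning)
        return last_fit


def _trace_record(stage, effect, estimate, se, p, threshold, retained, reason) -> dict:
    return {
        "stage": stage,
        "effect": str(effect),
        "target": effect.target,
        "item": effect.item,
        "covariate": effect.covariate,
        "estimate": estimate,
        "se": se,
        "p": p,
        "threshold": threshold,
        "retained": bool(retained),
        "reason": reason,
    }


@dataclass
class PipelineResult:
    final_fit: FitResult
    final_units: list[UnitKey]
    trace: pd.DataFrame

    @property
    def final_effects(self) -> list[EffectKey]:
        return [m for u in self.final_units for m in u.members()]

    @property
    def measurement_effects(self) -> list[EffectKey]:
        return [e for e in self.final_effects if e.target in ("intercept", "loading")]

    @property
    def measurement_invariant(self) -> bool:
        return not self.measurement_effects


def run_pipeline(table, design, config: SelectionConfig | None = None) -> PipelineResult:
    """Execute impact -> item DIF -> conditional -> FDR trimming on one dataset."""
    config = config or SelectionConfig()
    config.validate()
    trace: list[dict] = []
    impact_units, _ = impact_step(table, design, config, trace)
    dif_units, screen_pvalues = item_dif_step(table, design, impact_units, config, trace)
    carried = list(impact_units) + list(dif_units)
    structural, measurement, cond_fit = conditional_step(
        table, design, carried, config, trace, screen_pvalues
    )
    final_fit, final_units = fdr_trim(
        table, design, structural, measurement, cond_fit, config, trace
    )
    return PipelineResult(
        final_fit=final_fit,
        final_units=sorted(final_units, key=str),
        trace=pd.DataFrame.from_records(trace),
    )
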