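"""Stage 3: scale scores, bias-adjusted factor scores, and weighted group comparisons.

Unadjusted scores follow the standard scoring procedure for the scale (the mean of
the seven item responses, range [1, 5]).  Adjusted scores are the posterior-mean
factor scores under the final (trimmed) MNLFA model, which remove the estimated
measurement bias from the comparison metric.

Group comparisons are made within three families — sex (1 pair), race/ethnicity
(3 pairs), intersectional identity (15 pairs) — using sampling-weighted means and
SDs, a Welch-type z test, Benjamini–Hochberg FDR at q = .05 within each family,
and Hedges' g with the usual small/medium/large thresholds (0.2 / 0.5 / 0.8).
Weights enter the means and SDs (frequency-weight normalisation); the raw group
counts are kept for the pooling degrees of freedom and the small-sample J
correction, so g stays well defined under non-integer weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import RACES, SEXES
from .dif import bh_fdr
from .mnlfa import FitResult, ITEM_COLUMNS, MNLFAParameters, posterior_factor_scores

__all__ = [
    "unadjusted_scale_score",
    "adjusted_scores",
    "build_score_table",
    "hedges_g",
    "weighted_group_stats",
    "categorize_effect",
    "pairwise_compare",
    "pre_post_report",
    "comparison_matrix",
]

FAMILIES = ("sex", "race", "intersectional")


def unadjusted_scale_score(table: pd.DataFrame) -> pd.Series:
    """Per-person mean of the 7 item responses; persons with any missing item are
    excluded (NaN), consistent with the listwise default."""
    items = table[list(ITEM_COLUMNS)]
    score = items.mean(axis=1)
    score[items.isna().any(axis=1)] = np.nan
    return score


def adjusted_scores(final_model: MNLFAParameters | FitResult, table, design) -> np.ndarray:
    """Posterior-mean factor scores under the final model."""
    params = final_model.params if isinstance(final_model, FitResult) else final_model
    return posterior_factor_scores(params, table, design)


def build_score_table(table: pd.DataFrame, final_model, design) -> pd.DataFrame:
    """Person-level table of unadjusted and adjusted scores with labels and weights."""
    out = pd.DataFrame(
        {
            "person_id": table.get("person_id", pd.RangeIndex(len(table))),
            "unadjusted": unadjusted_scale_score(table),
            "adjusted": adjusted_scores(final_model, table, design),
            "sex": table["sex"].astype(str),
            "race_ethnicity": table["race_ethnicity"].astype(str),
            "weight": table["weight"] if "weight" in table else 1.0,
        }
    )
    return out


def weighted_group_stats(scores: np.ndarray, weights: np.ndarray) -> tuple[float, float, int]:
    """Weighted mean, frequency-weight SD, and raw count.

    SD uses the frequency-weight normalisation sum(w (x - m)^2) / (sum(w) - 1),
    which reduces to the classical unbiased SD at unit weights and is invariant
    to duplicating a person versus doubling their weight.
    """
    x = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = np.isfinite(x)
    x, w = x[keep], w[keep]
    if x.size == 0:
        raise ValueError("empty group")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = w.sum()
    m = float((w * x).sum() / sw)
    if x.size > 1:
        sd = float(np.sqrt((w * (x - m) ** 2).sum() / (sw - 1.0)))
    else:
        sd = 0.0
    return m, sd, int(x.size)


def hedges_g(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Standardised mean difference with the small-sample correction
    J = 1 - 3/(4(n1+n2) - 9) applied to the pooled-SD Cohen's d."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("group SDs must be nonnegative and not both zero")
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("pooled SD is zero")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (m1 - m2) / s_pooled)


def categorize_effect(g: float) -> str:
    """|g| in [0.2, 0.5) -> small; [0.5, 0.8) -> medium; >= 0.8 -> large."""
    a = abs(g)
    if not np.isfinite(a):
        raise ValueError("effect size must be finite")
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "below-small"


def _group_key(family: str, sex: str, race: str) -> str:
    if family == "sex":
        return sex
    if family == "race":
        return race
    return f"{race} {sex}"


def _family_groups(score_table: pd.DataFrame, family: str) -> dict[str, pd.DataFrame]:
    if family == "sex":
        keys = score_table["sex"]
    elif family == "race":
        keys = score_table["race_ethnicity"]
    elif family == "intersectional":
        keys = score_table["race_ethnicity"] + " " + score_table["sex"]
    else:
        raise ValueError(f"unknown comparison family {family!r}")
    return {str(k): grp for k, grp in score_table.groupby(keys)}


def pairwise_compare(score_table: pd.DataFrame, which: str = "unadjusted",
                     q: float = 0.05, families=FAMILIES) -> pd.DataFrame:
    """All pairwise weighted group comparisons, FDR-corrected within each family.

    Returns one row per ordered-as-listed pair with weighted means/SDs/Ns,
    Hedges' g, Welch-type z p-value, the within-family BH flag at level ``q``,
    and the effect-size category ("ns" for pairs not surviving FDR).
    """
    if which not in ("unadjusted", "adjusted"):
        raise ValueError("which must be 'unadjusted' or 'adjusted'")
    rows = []
    for family in families:
        groups = _family_groups(score_table, family)
        if len(groups) < 2:
            continue
        stats_by_group = {
            k: weighted_group_stats(g[which].to_numpy(), g["weight"].to_numpy())
            for k, g in groups.items()
        }
        for g1, g2 in itertools.combinations(sorted(groups), 2):
            m1, s1, n1 = stats_by_group[g1]
            m2, s2, n2 = stats_by_group[g2]
            se = np.sqrt(s1**2 / n1 + s2**2 / n2)
            z = (m1 - m2) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "family": family,
                    "group1": g1,
                    "group2": g2,
                    "mean1": m1, "sd1": s1, "n1": n1,
                    "mean2": m2, "sd2": s2, "n2": n2,
                    "g": hedges_g(m1, s1, n1, m2, s2, n2),
                    "z": float(z),
                    "p": float(p),
                }
            )
    report = pd.DataFrame.from_records(rows)
    if report.empty:
        raise ValueError("need at least two groups to compare")
    report["significant"] = False
    for family in report["family"].unique():
        idx = report["family"] == family
        report.loc[idx, "significant"] = bh_fdr(report.loc[idx, "p"].to_numpy(), q=q)
    report["category"] = [
        categorize_effect(g) if sig else "ns"
        for g, sig in zip(report["g"], report["significant"])
    ]
    report.insert(0, "which", which)
    return report


def pre_post_report(unadjusted_report: pd.DataFrame, adjusted_report: pd.DataFrame) -> pd.DataFrame:
    """Pair-by-pair contrast of unadjusted vs adjusted effect sizes.

    Flags category shifts (e.g. small -> medium) between the two scoring methods.
    """
    key = ["family", "group1", "group2"]
    a = unadjusted_report.set_index(key)
    b = adjusted_report.set_index(key)
    if not a.index.equals(b.index):
        raise ValueError("reports cover different pairings")
    out = pd.DataFrame(
        {
            "g_unadjusted": a["g"],
            "g_adjusted": b["g"],
            "delta_g": b["g"] - a["g"],
            "category_unadjusted": a["category"],
            "category_adjusted": b["category"],
        }
    )
    out["category_shift"] = [
        f"{cu}->{ca}" if cu != ca else ""
        for cu, ca in zip(out["category_unadjusted"], out["category_adjusted"])
    ]
    return out.reset_index()


def comparison_matrix(unadjusted_report: pd.DataFrame, adjusted_report: pd.DataFrame,
                      family: str = "intersectional") -> pd.DataFrame:
    """Square matrix of one family's effect sizes: unadjusted g above the diagonal,
    adjusted g below, 'ns' for non-significant pairs, group n on the diagonal."""
    ua = unadjusted_report[unadjusted_report["family"] == family]
    ad = adjusted_report[adjusted_report["family"] == family]
    names = sorted(set(ua["group1"]) | set(ua["group2"]))
    M = pd.DataFrame("", index=names, columns=names)
    for _, r in ua.iterrows():
        M.loc[r["group1"], r["group2"]] = (
            f"{r['g']:.3f}" if r["significant"] else "ns"
        )
        M.loc[r["group1"], r["group1"]] = f"n={r['n1']}"
        M.loc[r["group2"], r["group2"]] = f"n={r['n2']}"
    for _, r in ad.iterrows():
        M.loc[r["group2"], r["group1"]] = (
            f"{r['g']:.3f}" if r["significant"] else "ns"
        )
    return M
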