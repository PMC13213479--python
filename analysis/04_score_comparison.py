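#!/usr/bin/env python
"""Stage 3: unadjusted vs bias-adjusted scores and weighted group comparisons.

Scores the Likert cohort two ways - the standard scale score (mean of the seven
items) and the posterior factor score under the final MNLFA model from stage 2 -
then runs all weighted pairwise comparisons (sex, race/ethnicity, intersectional)
with Hedges' g and a 5% FDR per family, and contrasts pre- vs post-adjustment
effect sizes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pdsmeq.contrasts import build_design  # noqa: E402
from pdsmeq.io import load_params, read_response_table  # noqa: E402
from pdsmeq.scoring import (  # noqa: E402
    build_score_table,
    comparison_matrix,
    pairwise_compare,
    pre_post_report,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis_data"


def main() -> None:
    cohort, params = DATA / "cohort.csv", OUT / "final_params_likert.json"
    if not cohort.exists() or not params.exists():
        raise SystemExit("run 01_simulate_cohort.py and 03_dif_selection.py first")
    table = read_response_table(cohort)
    design = build_design(table)
    final = load_params(params)

    scores = build_score_table(table, final, design)
    scores.to_csv(DATA / "scores.csv", index=False)

    unadj = pairwise_compare(scores, "unadjusted")
    adj = pairwise_compare(scores, "adjusted")
    unadj.to_csv(OUT / "comparisons_unadjusted.csv", index=False)
    adj.to_csv(OUT / "comparisons_adjusted.csv", index=False)

    contrast = pre_post_report(unadj, adj)
    contrast.to_csv(OUT / "pre_post_contrast.csv", index=False)

    matrix = comparison_matrix(unadj, adj)
    matrix.to_csv(OUT / "comparison_matrix_intersectional.csv")

    print("group means (unadjusted | adjusted):")
    print(scores.groupby(["race_ethnicity", "sex"])[["unadjusted", "adjusted"]]
          .mean().round(3).to_string())
    print("\nrace/ethnicity family:")
    cols = ["group1", "group2", "g_unadjusted", "g_adjusted",
            "category_unadjusted", "category_adjusted", "category_shift"]
    print(contrast[contrast["family"] == "race"][cols].round(3).to_string(index=False))
    print("\nintersectional matrix (unadjusted above diagonal, adjusted below):")
    print(matrix.to_string())
    print(f"\noutputs in {OUT}")


if __name__ == "__main__":
    main()
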