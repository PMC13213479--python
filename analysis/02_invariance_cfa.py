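#!/usr/bin/env python
"""Stage 1: multiple-group CFA invariance screen across the six cells.

Fits configural, metric, and scalar one-factor models to the simulated cohort,
reports chi-square / CFI / RMSEA (90% CI) per level and the nested-model
decisions (delta-CFI > .01, chi-square difference p < .05, disjoint RMSEA CIs).
With sex intercept DIF in the generating model, the scalar level is expected to
show a fit decrement, motivating the MNLFA stage.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from pdsmeq.io import read_response_table  # noqa: E402
from pdsmeq.mgcfa import LEVELS, comparison_table, fit_mgcfa, nested_comparison  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis_data"


def main() -> None:
    cohort = DATA / "cohort.csv"
    if not cohort.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    table = read_response_table(cohort)

    fits = {lv: fit_mgcfa(table, level=lv) for lv in LEVELS}
    indices = comparison_table(fits)
    indices.to_csv(OUT / "mgcfa_fit_indices.csv", index=False)

    comps = pd.DataFrame(
        [
            {"comparison": "metric_vs_configural",
             **nested_comparison(fits["configural"], fits["metric"])},
            {"comparison": "scalar_vs_metric",
             **nested_comparison(fits["metric"], fits["scalar"])},
        ]
    )
    comps.to_csv(OUT / "mgcfa_nested_comparisons.csv", index=False)

    print(indices.round(4).to_string(index=False))
    print()
    print(comps.round(4).to_string(index=False))
    print(f"\noutputs in {OUT}")


if __name__ == "__main__":
    main()
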