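#!/usr/bin/env python
"""Monte-Carlo validation: parameter recovery and selection-pattern rates.

Runs (a) the 50-replicate recovery study of the two sex intercept-moderation
coefficients at n = 9,360 and (b) 20-replicate selection-pattern studies under
the final-model and null scenarios, on the generator's continuous output where
the fitted model class matches the generating process.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402

from pdsmeq.experiments import pattern_study, recovery_study  # noqa: E402
from pdsmeq.synthetic import KAPPA_ITEM1_SEX, KAPPA_ITEM3_SEX  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    est = recovery_study(n_reps=50, seed=SEED)
    est.to_csv(OUT / "recovery_estimates.csv", index=False)
    for col, truth in (("kappa_item1_sex", KAPPA_ITEM1_SEX),
                       ("kappa_item3_sex", KAPPA_ITEM3_SEX)):
        m, se = est[col].mean(), est[col].std(ddof=1) / np.sqrt(len(est))
        print(f"{col}: mean={m:.4f} (truth {truth}), MC se={se:.4f}")

    final = pattern_study("final_model", n_reps=20, seed=SEED + 1)
    final.per_replicate.to_csv(OUT / "pattern_final_model.csv", index=False)
    print(f"\nfinal_model: exact two-sex-intercept pattern in "
          f"{final.exact_pattern_rate:.0%} of {final.n_reps} replicates")

    null = pattern_study("null", n_reps=40, seed=SEED + 2)
    null.per_replicate.to_csv(OUT / "pattern_null.csv", index=False)
    print(f"null: measurement-invariant final model in "
          f"{null.invariant_rate:.0%} of {null.n_reps} replicates")
    print(f"\noutputs in {OUT}")


if __name__ == "__main__":
    main()
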