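#!/usr/bin/env python
"""Trial-wise statistics: does a trial's dopamine ramp slope track the
preceding ITI?

Reads the cohort trial table written by 02_generate_cohort.py and runs the
full statistical battery on the short-ITI/dynamic (SD) sessions: per-animal
regression of ramp slope on previous ITI, the pooled regression on
within-animal z-scored slopes, the consecutive-trial delta analysis, the
average-previous-ITI variant (k = 1..5), and the SD-vs-LD condition
comparison of mean ramp slopes.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ramplight import behavior

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    path = OUT / "trial_tables.csv"
    if not path.exists():
        raise SystemExit("run analysis/02_generate_cohort.py first (no trial_tables.csv)")
    table = pd.read_csv(path)
    sd = table[table.condition == "SD"]
    animals = sorted(sd.animal_id.unique())

    rows = []
    betas = []
    for a in animals:
        tab = sd[sd.animal_id == a]
        rep = behavior.previous_iti_beta(tab)
        betas.append(rep.beta)
        delta = behavior.delta_iti_analysis(tab)
        rows.append(
            {
                "animal_id": a,
                "beta_prev_iti": rep.beta,
                "beta_se": rep.se,
                "beta_p": rep.p_value,
                "beta_delta": delta["beta_delta"],
                "delta_slope_decrease": delta["mean_delta_slope_decrease"],
                "delta_slope_increase": delta["mean_delta_slope_increase"],
            }
        )
    per_animal = pd.DataFrame(rows)
    t_beta = stats.ttest_1samp(betas, 0.0)
    print(
        f"Per-animal previous-ITI beta: mean {np.mean(betas):+.4f} "
        f"(true -0.045), t({len(betas) - 1})={t_beta.statistic:.2f}, "
        f"p={t_beta.pvalue:.2g}"
    )

    pooled = behavior.pooled_zscore_beta(
        {a: sd[sd.animal_id == a] for a in animals}
    )
    print(
        f"Pooled z-scored beta: {pooled.beta:+.4f} +- {pooled.se:.4f} "
        f"(p={pooled.p_value:.2g}, n={pooled.n} trials)"
    )

    dec = per_animal.delta_slope_decrease
    inc = per_animal.delta_slope_increase
    cmp_delta = behavior.condition_comparison(dec, inc)
    print(
        f"Delta slope for ITI decreases vs increases: "
        f"{dec.mean():+.4f} vs {inc.mean():+.4f} (p={cmp_delta['p_value']:.2g})"
    )

    k_rows = []
    for k in range(1, 6):
        ks = [behavior.average_prev_iti_beta(sd[sd.animal_id == a], k).beta for a in animals]
        t = stats.ttest_1samp(ks, 0.0)
        k_rows.append({"k_back": k, "mean_beta": np.mean(ks), "p": t.pvalue})
        print(f"  avg of {k} previous ITIs: mean beta {np.mean(ks):+.4f} (p={t.pvalue:.2g})")

    mean_sd = sd.groupby("animal_id")["ramp_slope"].mean()
    mean_ld = table[table.condition == "LD"].groupby("animal_id")["ramp_slope"].mean()
    cmp_cond = behavior.condition_comparison(mean_sd[animals], mean_ld[animals])
    print(
        f"SD vs LD mean ramp slope: {mean_sd.mean():+.4f} vs {mean_ld.mean():+.4f} "
        f"%dF/F per s (paired p={cmp_cond['p_value']:.2g})"
    )

    per_animal.to_csv(OUT / "per_animal_betas.csv", index=False)
    pd.DataFrame(k_rows).to_csv(OUT / "avg_prev_iti_betas.csv", index=False)
    summary = pd.DataFrame(
        [
            {"analysis": "pooled_zscore_beta", "value": pooled.beta, "p": pooled.p_value},
            {"analysis": "per_animal_beta_mean", "value": np.mean(betas), "p": t_beta.pvalue},
            {"analysis": "sd_vs_ld_slope_diff", "value": mean_sd.mean() - mean_ld.mean(),
             "p": cmp_cond["p_value"]},
        ]
    )
    summary.to_csv(OUT / "trialwise_stats.csv", index=False)


if __name__ == "__main__":
    main()
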