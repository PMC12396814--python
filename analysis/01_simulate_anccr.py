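#!/usr/bin/env python
"""Simulate ANCCR dopamine responses for the short- and long-ITI dynamic
cue conditions and quantify the within-trial ramp.

Runs 20 iterations x 1000 trials per condition with the standard parameters
(w=0.5, b_cues=0, b_reward=0.5, threshold=0.2, T=0.2*IRI, alpha0=5e-3,
alphaR=1, dt=0.2 s), analyzes the last 100 trials of each iteration, and
writes the iteration-averaged response curves and ramp metrics.

Finding: with the eligibility time constant tied to the inter-reward
interval, the model ramps across the cue sequence only when the ITI is
short; a long ITI instead concentrates the response at cue onset.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ramplight.anccr import (
    ANCCRParams,
    per_iteration_ramp_slopes,
    run_simulation,
    simulation_ramp_metrics,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 101) -> None:
    OUT.mkdir(exist_ok=True)
    params = ANCCRParams()
    rows, curves = [], []
    for i, condition in enumerate(("sim-short", "sim-long")):
        result = run_simulation(condition, params, seed=seed + i)
        metrics = simulation_ramp_metrics(result)
        slopes = per_iteration_ramp_slopes(result)
        rows.append(
            {
                "condition": condition,
                "ramp_slope": metrics["slope"],
                "ramp_slope_iter_sd": slopes.std(ddof=1),
                "onset_response": metrics["onset_response"],
                "n_iterations": params.n_iterations,
                "n_analysis_trials": params.n_analysis_trials,
            }
        )
        mean = result.mean_response()
        for lab, t, v in zip(result.event_labels, result.event_times_in_trial, mean):
            curves.append(
                {"condition": condition, "event_label": lab,
                 "time_in_trial_s": t, "mean_dopamine": v}
            )
        print(
            f"{condition}: ramp slope {metrics['slope']:+.4f} /s "
            f"(iteration SD {slopes.std(ddof=1):.4f}), "
            f"onset response {metrics['onset_response']:+.4f}"
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "simulation_summary.csv", index=False)
    pd.DataFrame(curves).to_csv(OUT / "simulation_curves.csv", index=False)
    short, long_ = summary.iloc[0], summary.iloc[1]
    print(
        f"\nRamp only with short ITI: slope {short.ramp_slope:+.4f} vs "
        f"{long_.ramp_slope:+.4f}; onset response larger with long ITI "
        f"({long_.onset_response:+.4f} vs {short.onset_response:+.4f})."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 101)
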