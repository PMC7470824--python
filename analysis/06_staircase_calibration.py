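"""Adaptive staircase calibration of the simulated listener.

Runs the 1-up-3-down track for a bank of logistic observers and verifies the
converged level sits at the 79.4% point of each psychometric function.
Writes results/staircase.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import RESULTS

from megword import staircase


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    target = staircase.target_probability(3)
    rows = []
    rng = np.random.default_rng(794)
    for i in range(12):
        midpoint = float(rng.uniform(-9.0, -3.0))  # dB SNR threshold
        slope = float(rng.uniform(0.3, 0.6))
        observer = staircase.logistic_observer(midpoint, slope)
        track = staircase.run_staircase(
            observer, start_level=0.0, step=1.0, n_reversals=None,
            n_trials=4000, n_converge=30, seed=i,
        )
        rows.append(
            {
                "observer": i,
                "midpoint_db": midpoint,
                "slope_per_db": slope,
                "converged_level_db": track.converged_level,
                "p_correct_at_convergence": observer(track.converged_level),
                "n_reversals": track.n_reversals,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "staircase.tsv", sep="\t", index=False)

    mean_p = table["p_correct_at_convergence"].mean()
    print(f"1-up-3-down analytic target: {100 * target:.1f}% correct")
    print(f"mean observer accuracy at the converged level: {100 * mean_p:.1f}% "
          f"(SD {100 * table['p_correct_at_convergence'].std():.1f}%)")
    print(f"wrote {RESULTS / 'staircase.tsv'}")


if __name__ == "__main__":
    main()
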