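#!/usr/bin/env python
"""Simulate the study-like birth cohort and write it to results/cohort/.

The generator reproduces the design: visits at 0.25-6 y, ~6/14/35% dropout
by 1/2/6 y, Table-1 covariate prevalences, J-shaped intake medians, and
events from a piecewise-constant baseline hazard with current-value
association (~4.4% islet autoimmunity, ~1.7% T1D by age 6).
"""

from pathlib import Path

from fajoint.reporting import write_cohort
from fajoint.simulate import default_truth, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

if __name__ == "__main__":
    truth = default_truth()
    children, records = generate_cohort(truth, 6000, seed=20041996,
                                        all_variables=True)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort(children, records, OUT / "children.csv", OUT / "records.csv")
    print(f"simulated {len(children)} children, {len(records)} food records")
    print(f"islet autoimmunity: {100 * children.ia_status.mean():.1f}%  "
          f"T1D: {100 * children.t1d_status.mean():.1f}%  "
          f"record days/child: {records.n_days.sum() / len(children):.1f}")
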