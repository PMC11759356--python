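"""Summarize pupil-area traces: blink repair, group means over the task
period, percent difference, and time-locked averages.

Finding expected: FM-like mean area ~1920 pixel units vs ~1540 for HC-like,
about 25% larger, with stimulation-locked dilation in both group averages.
"""

from pathlib import Path

import pandas as pd

from sapm.pupil import average_trace, group_mean_area, repair_blinks
from sapm.synth import PUPIL_DEFAULTS, PupilGroupParams, simulate_pupil

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "08_pupil"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    traces = []
    for i, (group, n_trials) in enumerate((("FM", 40), ("HC", 25))):
        params = PupilGroupParams(**{**PUPIL_DEFAULTS[group].__dict__,
                                     "blink_rate_hz": 0.05})
        traces += simulate_pupil(params, n_trials, seed=SEED + i, fs=100.0,
                                 group=group, n_participants=8)
    traces = [repair_blinks(t) for t in traces]
    summary = group_mean_area(traces)
    print("Group mean pupil areas (task period, pixel units):",
          {g: round(m, 1) for g, m in summary.group_means.items()})
    print(f"FM exceeds HC by {summary.percent_difference:.1f}%")

    rows = []
    for group in ("FM", "HC"):
        grid, mean, sem = average_trace([t for t in traces if t.group == group],
                                        grid_fs=2.0)
        rows.append(pd.DataFrame({"time_s": grid, "group": group,
                                  "mean_area": mean, "sem": sem}))
    pd.concat(rows).to_csv(OUT / "average_traces.tsv", sep="\t", index=False)
    pd.DataFrame([{"group": g, "mean_area": m,
                   "n_trials": summary.n_trials[g]}
                  for g, m in summary.group_means.items()]
                 ).to_csv(OUT / "group_summary.tsv", sep="\t", index=False)
    print("Averaged traces and summary written to", OUT)


if __name__ == "__main__":
    main()
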