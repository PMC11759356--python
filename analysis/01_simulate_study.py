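"""Simulate the synthetic study: threat/safety runs for FM-like and HC-like
groups on the 14-region brain network.

Writes a per-run BOLD sample and a study summary under results/.
"""

import json
from pathlib import Path

import numpy as np

from sapm import io as sio
from sapm.design import ParadigmSpec, make_paradigm
from sapm.network import load_builtin_network
from sapm.synth import SimulationConfig, simulate_bold

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "01_simulate"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    net = load_builtin_network("brain")
    cfg = SimulationConfig(network=net, n_participants={"FM": 4, "HC": 4},
                           n_runs=3, seed=SEED)
    studies = {}
    for i, cond in enumerate(("Pain", "NoPain")):
        par, indicator = make_paradigm(cond)
        studies[cond] = simulate_bold(cfg, par, seed=SEED + i)
        np.savetxt(OUT / f"stimulus_indicator_{cond}.tsv", indicator, fmt="%d")

    run = studies["Pain"].runs[0]
    sio.write_timecourses(
        run.values, list(net.regions),
        {"participant": run.participant, "group": run.group, "run": run.run,
         "condition": run.condition, "TR": run.TR},
        OUT / "example_run.tsv",
    )
    summary = {
        "network": net.name,
        "n_regions": net.n_regions,
        "n_connections": len(net.connections),
        "volumes_per_run": studies["Pain"].paradigm.n_volumes,
        "runs_simulated": {c: len(s.runs) for c, s in studies.items()},
        "noise_sd_percent": cfg.noise_sd,
        "rise_amplitude_percent": cfg.rise_amplitude,
        "rise_group_multiplier": cfg.rise_group_multiplier,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print("Simulated", sum(len(s.runs) for s in studies.values()),
          "runs across Pain/NoPain;", summary["volumes_per_run"], "volumes each.")
    print("Example run and stimulus indicators written to", OUT)


if __name__ == "__main__":
    main()
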