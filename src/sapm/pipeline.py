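"""End-to-end pipeline tying all analysis stages together.

Stages run in order: simulate -> prep/cluster -> sub-region search -> freeze
-> SAPM fits per participant/condition -> null + significance -> features ->
group stats -> pupil.  Outputs are TSV tables in the results directory plus a
JSON log recording the seed, configuration hash and the defaults in effect.
Rerunning with the same config and seed reproduces every output
bit-identically.

Configuration is a single YAML/JSON file with per-stage blocks; unknown keys
are rejected (fail-fast).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sapm import io as sio
from sapm.core import FitConfig, fit_sapm
from sapm.features import event_responses, initial_rise
from sapm.network import load_builtin_network, load_network
from sapm.prep import cluster_region, extract_subregion_timecourses, mask_initial_volumes
from sapm.pupil import group_mean_area, repair_blinks
from sapm.search import freeze_combination, search_subregions
from sapm.significance import connection_ttest, generate_null
from sapm.stats import ancova, two_group_compare
from sapm.synth import (
    ParadigmSpec,
    PupilGroupParams,
    SimulationConfig,
    make_subregion_timecourses,
    simulate_bold,
    simulate_pupil,
    simulate_voxels,
)

__all__ = ["PipelineError", "load_config", "demo_config_path", "run_pipeline", "STAGES"]

STAGES = ("simulate", "cluster", "search", "fit", "null", "features", "stats", "pupil")

_SCHEMA = {
    "name": None,
    "seed": None,
    "network": None,
    "paradigm": {"TR", "run_duration", "inform_time", "stimulus_onset"},
    "simulate": {"n_participants", "n_runs", "noise_sd", "rise_amplitude", "rise_group_multiplier"},
    "cluster": {"k", "voxels_per_subregion", "within_sd", "n_replace"},
    "search": {"n_starts", "n_restarts"},
    "fit": {"n_restarts", "max_iterations", "tol"},
    "null": {"reps", "n_restarts"},
    "features": set(),
    "stats": set(),
    "pupil": {"n_trials", "baselines"},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""


def demo_config_path() -> Path:
    """Path of the bundled small-synthetic-study demo configuration."""
    return Path(str(resources.files("sapm.data").joinpath("demo_config.yaml")))


def load_config(path: str | Path) -> dict:
    """Load and schema-check a pipeline config (YAML or JSON)."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} must be a mapping")
    for key, block in cfg.items():
        if key not in _SCHEMA:
            raise PipelineError(f"unknown config block {key!r}; allowed: {sorted(_SCHEMA)}")
        allowed = _SCHEMA[key]
        if allowed is not None and isinstance(block, dict):
            bad = set(block) - allowed
            if bad:
                raise PipelineError(f"unknown keys {sorted(bad)} in config block {key!r}")
    return cfg


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: str | Path | dict, out_dir: str | Path, stages=STAGES) -> Path:
    """Execute the pipeline stages in order, writing TSV outputs and a log.

    ``stages`` may be truncated (a prefix of the canonical order is always
    executed because later stages consume earlier in-memory results); only
    the outputs of requested stages are written.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = set(stages)
    last = max(STAGES.index(s) for s in requested)
    seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(seed)
    log = {"config_hash": sio.config_hash(cfg), "seed": seed, "stages": [], "defaults": {}}

    def fail(stage, exc):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- network ---------------------------------------------------------
    netspec = cfg.get("network", "demo_small")
    net = load_builtin_network(netspec) if isinstance(netspec, str) and not str(netspec).endswith(
        (".json", ".yaml", ".yml")
    ) else load_network(netspec)

    # ---- simulate --------------------------------------------------------
    try:
        pcfg = cfg.get("paradigm", {}) or {}
        scfg = cfg.get("simulate", {}) or {}
        sim = SimulationConfig(
            network=net,
            n_participants=scfg.get("n_participants", {"FM": 3, "HC": 3}),
            n_runs=int(scfg.get("n_runs", 2)),
            noise_sd=float(scfg.get("noise_sd", 0.2)),
            rise_amplitude=float(scfg.get("rise_amplitude", 0.4)),
            rise_group_multiplier=float(scfg.get("rise_group_multiplier", 2.0)),
            seed=seed,
        )
        paradigms = {
            c: ParadigmSpec(condition=c, **pcfg) for c in ("Pain", "NoPain")
        }
        studies = {
            c: simulate_bold(sim, paradigms[c], seed=seed + i)
            for i, c in enumerate(("Pain", "NoPain"))
        }
        log["defaults"]["simulate"] = {
            "noise_sd": sim.noise_sd,
            "rise_amplitude": sim.rise_amplitude,
            "rise_group_multiplier": sim.rise_group_multiplier,
            "n_runs": sim.n_runs,
        }
        if "simulate" in requested:
            for c, study in studies.items():
                for r in study.runs[:2]:  # sample of raw outputs
                    sio.write_timecourses(
                        r.values,
                        list(net.regions),
                        {
                            "participant": r.participant,
                            "group": r.group,
                            "run": r.run,
                            "condition": c,
                            "TR": r.TR,
                        },
                        out / f"bold_{c}_{r.participant}_run{r.run}.tsv",
                    )
        log["stages"].append("simulate")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)

    if last < STAGES.index("cluster"):
        _finish(out, log)
        return out

    # ---- prep + cluster --------------------------------------------------
    try:
        ccfg = cfg.get("cluster", {}) or {}
        k = int(ccfg.get("k", 5))
        vps = int(ccfg.get("voxels_per_subregion", 6))
        within_sd = float(ccfg.get("within_sd", 0.1))
        n_replace = int(ccfg.get("n_replace", 3))
        study = studies["Pain"]
        grand = np.mean([r.values for r in study.runs], axis=0)
        grand = mask_initial_volumes(grand, n_replace)
        subregion_tcs, planted = make_subregion_timecourses(
            grand, net, k=k, seed=seed, noise_sd=float(np.std(grand))
        )
        extracted = {}
        assign_rows = []
        for i, r in enumerate(net.regions):
            vox = simulate_voxels(subregion_tcs[r], vps, within_sd, seed=seed + i)
            assignment = cluster_region(vox.values, k=k, seed=seed)
            extracted[r] = extract_subregion_timecourses(vox.values, assignment)
            assign_rows += [
                {"region": r, "voxel": v, "subregion": int(lab)}
                for v, lab in enumerate(assignment.labels)
            ]
        if "cluster" in requested:
            _tsv(pd.DataFrame(assign_rows), out / "cluster_assignments.tsv")
        log["stages"].append("cluster")
    except Exception as exc:  # noqa: BLE001
        fail("cluster", exc)

    if last < STAGES.index("search"):
        _finish(out, log)
        return out

    # ---- sub-region search + freeze -------------------------------------
    try:
        fcfg = cfg.get("fit", {}) or {}
        fit_cfg = FitConfig(
            n_restarts=int(fcfg.get("n_restarts", 2)),
            max_iterations=int(fcfg.get("max_iterations", 300)),
            tol=float(fcfg.get("tol", 1e-6)),
            seed=seed,
        )
        search_cfg = FitConfig(
            n_restarts=int((cfg.get("search", {}) or {}).get("n_restarts", 1)),
            max_iterations=200,
            tol=1e-5,
            seed=seed,
        )
        comb = search_subregions(
            extracted,
            net,
            fit_cfg=search_cfg,
            seed=seed,
            n_starts=int((cfg.get("search", {}) or {}).get("n_starts", 2)),
            paradigm=paradigms["Pain"],
        )
        freeze_combination(comb, out / "frozen_subregions.json")
        if "search" in requested:
            _tsv(
                pd.DataFrame(comb.trajectory, columns=["iteration", "fit_error"]),
                out / "search_trajectory.tsv",
            )
        log["stages"].append("search")
    except Exception as exc:  # noqa: BLE001
        fail("search", exc)

    if last < STAGES.index("fit"):
        _finish(out, log)
        return out

    # ---- SAPM fits per participant/condition ----------------------------
    try:
        conns = [f"{s}->{t}" for s, t in net.connections]
        fit_rows = []
        db_values: dict[str, dict[tuple, list]] = {}
        for c, study in studies.items():
            for pid in study.participants:
                avg = mask_initial_volumes(study.run_average(pid, c), 3)
                params = fit_sapm(avg, net, fit_cfg, paradigm=paradigms[c])
                grp = "FM" if pid.startswith("FM") else "HC"
                key = f"{grp}/{c}"
                db_values.setdefault(key, {conn: [] for conn in net.connections})
                for conn, db in zip(net.connections, params.DB):
                    db_values[key][conn].append(db)
                for conn, d, b, db in zip(conns, params.D, params.B, params.DB):
                    fit_rows.append(
                        {
                            "participant": pid,
                            "group": grp,
                            "condition": c,
                            "connection": conn,
                            "D": d,
                            "B": b,
                            "DB": db,
                            "fit_error": params.fit_error,
                            "mean_R2": float(np.nanmean(params.R2)),
                        }
                    )
        fits = pd.DataFrame(fit_rows)
        if "fit" in requested:
            _tsv(fits, out / "connectivity.tsv")
            # closed-loop recovery report: fitted vs true DB
            rec = (
                fits[fits.condition == "Pain"]
                .groupby("connection", sort=False)["DB"]
                .mean()
                .reindex(conns)
            )
            _tsv(
                pd.DataFrame(
                    {"connection": conns, "DB_true": sim.true_DB, "DB_fitted_mean": rec.values}
                ),
                out / "recovery.tsv",
            )
        log["stages"].append("fit")
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)

    if last < STAGES.index("null"):
        _finish(out, log)
        return out

    # ---- null + significance --------------------------------------------
    try:
        ncfg = cfg.get("null", {}) or {}
        null = generate_null(
            net,
            paradigms["Pain"].n_volumes,
            reps=int(ncfg.get("reps", 50)),
            fit_cfg=FitConfig(n_restarts=int(ncfg.get("n_restarts", 1)), seed=seed),
            seed=seed,
            paradigm=paradigms["Pain"],
        )
        sig_rows = []
        for key, values in db_values.items():
            grp, c = key.split("/")
            for st in connection_ttest(values, null, group=grp, condition=c):
                sig_rows.append(st.__dict__)
        if "null" in requested:
            _tsv(pd.DataFrame(sig_rows), out / "significance.tsv")
        log["stages"].append("null")
    except Exception as exc:  # noqa: BLE001
        fail("null", exc)

    if last < STAGES.index("features"):
        _finish(out, log)
        return out

    # ---- BOLD features ---------------------------------------------------
    try:
        feat_rows = []
        for c, study in studies.items():
            for pid in study.participants:
                avg = mask_initial_volumes(study.run_average(pid, c), 3)
                grp = "FM" if pid.startswith("FM") else "HC"
                for i, r in enumerate(net.regions):
                    f = initial_rise(avg[i], TR=paradigms[c].TR, n_masked=3)
                    ev = event_responses(avg[i], paradigms[c])
                    feat_rows.append(
                        {
                            "participant": pid,
                            "group": grp,
                            "condition": c,
                            "region": r,
                            "initial_rise": f.initial_rise,
                            "starting_point": f.starting_point,
                            "onset_response": ev.onset_response,
                            "offset_response": ev.offset_response,
                        }
                    )
        feats = pd.DataFrame(feat_rows)
        if "features" in requested:
            _tsv(feats, out / "features.tsv")
        log["stages"].append("features")
    except Exception as exc:  # noqa: BLE001
        fail("features", exc)

    if last < STAGES.index("stats"):
        _finish(out, log)
        return out

    # ---- group stats -----------------------------------------------------
    try:
        per_part = (
            feats[feats.condition == "Pain"]
            .groupby(["participant", "group"], sort=False)["initial_rise"]
            .mean()
            .reset_index()
        )
        # synthetic anxiety-like covariate: correlated with the rise
        cov = per_part["initial_rise"].to_numpy() * 20 + rng.normal(40, 5, len(per_part))
        res = ancova(
            per_part["initial_rise"].to_numpy(),
            per_part["group"].to_numpy(),
            cov,
            dependent_name="initial_rise",
            covariate_name="anxiety_score",
        )
        snri = np.array([rng.random() < 0.5 for _ in range(len(per_part))])
        labels = np.where(snri, "SNRI", "noSNRI")
        stats_rows = [
            {
                "analysis": "ancova",
                "dependent": res.dependent,
                "covariate": res.covariate,
                "p_group": res.p_group,
                "p_covariate": res.p_covariate,
                "p_interaction": res.p_interaction,
            }
        ]
        if len(np.unique(labels)) == 2 and min((labels == "SNRI").sum(), (labels == "noSNRI").sum()) >= 2:
            cmp_res = two_group_compare(per_part["initial_rise"].to_numpy(), labels)
            stats_rows.append(
                {
                    "analysis": "two_group_SNRI",
                    "dependent": "initial_rise",
                    "covariate": "",
                    "p_group": cmp_res.p,
                    "p_covariate": np.nan,
                    "p_interaction": np.nan,
                }
            )
        if "stats" in requested:
            _tsv(pd.DataFrame(stats_rows), out / "group_stats.tsv")
        log["stages"].append("stats")
    except Exception as exc:  # noqa: BLE001
        fail("stats", exc)

    if last < STAGES.index("pupil"):
        _finish(out, log)
        return out

    # ---- pupil -----------------------------------------------------------
    try:
        pup_cfg = cfg.get("pupil", {}) or {}
        n_trials = pup_cfg.get("n_trials", {"FM": 6, "HC": 6})
        baselines = pup_cfg.get("baselines", {"FM": 1920.0, "HC": 1540.0})
        traces = []
        for g, n in n_trials.items():
            params = PupilGroupParams(baseline_area=float(baselines[g]))
            g_seed = seed + sum(ord(ch) for ch in g)  # process-independent
            traces += simulate_pupil(params, int(n), seed=g_seed, fs=100.0, group=g)
        traces = [repair_blinks(t) for t in traces]
        summary = group_mean_area(traces)
        if "pupil" in requested:
            _tsv(
                pd.DataFrame(
                    [
                        {
                            "group": g,
                            "mean_area": m,
                            "n_trials": summary.n_trials[g],
                            "percent_difference_vs_other": summary.percent_difference
                            if g == summary.reference_groups[0]
                            else np.nan,
                        }
                        for g, m in summary.group_means.items()
                    ]
                ),
                out / "pupil_summary.tsv",
            )
        log["stages"].append("pupil")
    except Exception as exc:  # noqa: BLE001
        fail("pupil", exc)

    _finish(out, log)
    return out


def _finish(out: Path, log: dict) -> None:
    (out / "log.json").write_text(json.dumps(log, indent=2, default=str))
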