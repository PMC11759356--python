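"""Synthetic data with the statistical structure the analysis assumes.

Generates paradigm timing (the threat/safety heat-pain design), latent drive
signals, network-propagated BOLD time series with known ground-truth D/B/DB
weightings, voxel-level datasets with planted 5-sub-region structure, and
pupil-area traces with white/black reference periods.

Study conditions emulated by the defaults
-----------------------------------------
* 4.5-minute runs; brain TR 2 s (135 volumes), brainstem/cord TR 6.75 s
  (40 volumes).
* Pain runs: participants informed at the 1-minute mark, then 10 heat contacts
  of 1.5 s with onsets every 3 s starting at the 2-minute mark (a 30-s block);
  No-Pain runs carry the inform cue only.
* A group-dependent initial rise over the first ~40 s of every run, about
  twice as large in the FM-like group as in the HC-like group.  The rise is
  modeled as an additive exogenous component common to all regions — i.e.
  outside the connectivity model — matching its interpretation as a
  widespread, possibly hormonally mediated, arousal signal rather than
  network-propagated signaling.
* Pupil traces at 500 Hz with white/black reference screens at both ends,
  group baseline areas of 1540 (HC-like) and 1920 (FM-like) pixel units, and
  dilation at run start and during stimulation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sapm.core import FitConfig, build_matrices, default_D, solve_forward, spectral_radius
from sapm.design import (
    RISE_TAU_DEFAULT,
    ParadigmSpec,
    build_latent_basis,
    hemodynamic_kernel,
    make_paradigm,
)
from sapm.network import NetworkModel, load_builtin_network

__all__ = [
    "ParadigmSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "VoxelDataset",
    "PupilTrace",
    "PupilGroupParams",
    "make_paradigm",
    "hemodynamic_kernel",
    "generate_latents",
    "simulate_bold",
    "make_subregion_timecourses",
    "simulate_voxels",
    "simulate_pupil",
    "default_brain_config",
    "canonical_true_B",
    "PUPIL_DEFAULTS",
    "RISE_TAU_DEFAULT",
]


@dataclass
class SimulationConfig:
    """Ground truth and noise structure for the BOLD simulator.

    true_B : per-connection signed conversion factors (aligned with
        ``network.connections``); DB = D * B with D the equal-split input
        fractions.  ``true_DB`` is the derived product.
    event_amplitude / drift_amplitude / rise_latent_amplitude : relative
        weights of the latent components (inform + stimulation events, smooth
        background drive, and a saturating early component) before each latent
        is standardized to unit variance.
    rise_amplitude : % signal change of the additive exogenous initial rise
        in the HC-like group; multiplied by ``rise_group_multiplier`` (default
        2) for the FM-like group.
    noise_sd : i.i.d. Gaussian noise s.d. in % signal change.
    """

    network: NetworkModel = None
    true_B: np.ndarray = None
    event_amplitude: float = 1.0
    drift_amplitude: float = 0.5
    rise_latent_amplitude: float = 0.08
    kernel_width: float = 1.0
    rise_amplitude: float = 0.4
    rise_tau: float = RISE_TAU_DEFAULT
    rise_group_multiplier: float = 2.0
    noise_sd: float = 0.2
    n_participants: dict = field(default_factory=lambda: {"FM": 20, "HC": 17})
    n_runs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.network is None:
            self.network = load_builtin_network("brain")
        if self.true_B is None:
            self.true_B = canonical_true_B(self.network)
        self.true_B = np.asarray(self.true_B, float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def true_D(self) -> np.ndarray:
        return default_D(self.network)

    @property
    def true_DB(self) -> np.ndarray:
        return self.true_D * self.true_B


#: default ground-truth DB values for the bundled brain network, taken from
#: reported group-average connectivity magnitudes for the FM-like Pain
#: condition where a connection was characterized, and mid-range values for
#: the anatomy-completion edges and latent inputs.
_BRAIN_TRUE_DB = {
    ("AC", "PC"): 0.402,
    ("IC", "AC"): 0.679,
    ("AC", "IC"): 0.275,
    ("Thal", "AC"): 0.276,
    ("Amyg", "Thal"): 0.311,
    ("Thal", "PC"): 0.326,
    ("PC", "AC"): 0.133,
    ("AC", "FOrb"): -0.253,
    ("PBN", "Thal"): 0.094,
    ("Hypo", "PAG"): 0.036,
    ("Thal", "Hypo"): 0.245,
    ("Amyg", "Hippo"): 0.098,
    ("LC", "PBN"): -0.050,
    ("Hypo", "Thal"): 0.340,
    ("LC", "Thal"): 0.347,
    ("AC", "Amyg"): 0.071,
    ("Thal", "Hippo"): 0.165,
    ("IC", "HG"): 0.340,
    ("Hypo", "VTA"): 0.300,
    ("VTA", "NAcc"): 0.300,
    ("Lat0", "FOrb"): 0.500,
    ("Lat1", "IC"): 0.500,
    ("Lat2", "LC"): 0.500,
}


def _default_true_B(net: NetworkModel) -> np.ndarray:
    D = default_D(net)
    db = np.array([_BRAIN_TRUE_DB.get(c, 0.3) for c in net.connections])
    return db / D


_CANONICAL_CACHE: dict = {}


def canonical_true_B(net: NetworkModel, b0: np.ndarray | None = None) -> np.ndarray:
    """Gauge-fixed ground-truth B for a network.

    Low-rank latent dynamics leave some weight combinations observationally
    equivalent: along those directions the model output is identical for any
    latent input, so no fit can distinguish them.  The fitting engine reports
    the minimal-norm representative of each equivalence class; the
    generator's ground truth is expressed in the same gauge so that
    simulate-then-fit recovery is well defined.  Starting from the nominal
    weights (reported group-mean connectivity magnitudes), a noiseless
    reference dataset is simulated and re-fitted from that exact starting
    point, sliding the weights along the flat directions to the canonical
    representative without changing the generated signals' fit.
    """
    from sapm.core import FitConfig, fit_sapm

    if b0 is None:
        b0 = _default_true_B(net)
    key = (net.name, tuple(net.connections), tuple(np.round(b0, 12)))
    if key not in _CANONICAL_CACHE:
        paradigm = ParadigmSpec()
        ref = SimulationConfig(network=net, true_B=b0, noise_sd=0.0)
        lat = generate_latents(paradigm, ref, seed=202_406)
        D = default_D(net)
        b = np.asarray(b0, float)
        # fixed point of simulate -> gauge-fixed refit: at convergence the
        # weights reproduce themselves exactly from their own noiseless data
        for _ in range(25):
            mats = build_matrices(net, D, b)
            _, s_in = solve_forward(mats, lat)
            fit = fit_sapm(
                s_in,
                net,
                FitConfig(n_restarts=1, tol=1e-14, max_iterations=3000),
                paradigm=paradigm,
                init_B=b,
            )
            step = np.max(np.abs((fit.B - b) * D))
            b = fit.B
            if step < 1e-7:
                break
        _CANONICAL_CACHE[key] = b
    return _CANONICAL_CACHE[key]


def default_brain_config(**overrides) -> SimulationConfig:
    """The simulator at its study-condition defaults (bundled brain network)."""
    return SimulationConfig(**overrides)


def generate_latents(
    paradigm: ParadigmSpec, config: SimulationConfig, seed: int,
    rise_scale: float = 1.0,
) -> np.ndarray:
    """Latent x time drive matrix, deterministic under ``seed``.

    Each latent is drawn from its own temporal basis (see
    :func:`sapm.design.build_latent_basis`): hemodynamically convolved
    event responses at the inform cue and stimulation onset/offset,
    convolved block/anticipation components, and a slow-arousal group with
    the saturating early component 1 - exp(-t/tau) plus low-order cosines.
    Coefficients are seeded random draws scaled by the configured
    amplitudes; ``rise_scale`` additionally multiplies the saturating
    component (the group-dependent arousal drive), and each nonzero latent
    is standardized to zero mean and unit variance.  Because the fitting
    engine estimates latents in the same basis class, simulate-then-fit
    recovery is exact in the noiseless limit.
    """
    rng = np.random.default_rng(seed)
    L = config.network.n_latents
    bases, kinds = build_latent_basis(
        paradigm,
        L,
        kernel_width=config.kernel_width,
        rise_tau=config.rise_tau,
        return_kinds=True,
    )
    latents = np.zeros((L, paradigm.n_volumes))
    amp_of = {
        "event": lambda: config.event_amplitude * rng.uniform(0.5, 1.5),
        "block": lambda: config.event_amplitude * rng.uniform(0.5, 1.5),
        "rise": lambda: rise_scale * config.rise_latent_amplitude * rng.uniform(0.5, 1.5),
        "cosine": lambda: config.drift_amplitude * 0.5 * rng.standard_normal(),
    }
    for j in range(L):
        theta = np.array([amp_of[k]() for k in kinds[j]])
        x = bases[j] @ theta
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
        latents[j] = x
    return latents


@dataclass
class RunTimecourses:
    """One simulated run: region x time observations plus ground truth."""

    values: np.ndarray  # (R, T) observed, % signal change
    network_signal: np.ndarray  # (R, T) noise-free S_input
    rise: np.ndarray  # (T,) additive exogenous rise component
    latents: np.ndarray  # (L, T)
    participant: str = ""
    group: str = ""
    condition: str = "Pain"
    run: int = 0
    TR: float = 2.0


@dataclass
class SimulatedStudy:
    """Collection of simulated runs with the generating configuration."""

    config: SimulationConfig
    paradigm: ParadigmSpec
    runs: list = field(default_factory=list)

    def select(self, **meta) -> list:
        out = self.runs
        for k, v in meta.items():
            out = [r for r in out if getattr(r, k) == v]
        return out

    def run_average(self, participant: str, condition: str) -> np.ndarray:
        """Run-averaged region x time matrix for one participant/condition
        (the default SAPM fit target)."""
        runs = self.select(participant=participant, condition=condition)
        if not runs:
            raise KeyError(f"no runs for participant={participant} condition={condition}")
        return np.mean([r.values for r in runs], axis=0)

    @property
    def participants(self) -> list[str]:
        seen = []
        for r in self.runs:
            if r.participant not in seen:
                seen.append(r.participant)
        return seen


def simulate_bold(
    config: SimulationConfig, paradigm: ParadigmSpec | None = None, seed: int | None = None
) -> SimulatedStudy:
    """Simulate the study: per participant, run, and region BOLD time courses.

    Noise-free network signal is the model's region input signal
    ``S_input = M_input S_output + D_latent latents`` with ``S_output``
    solving the latent-driven fixed point.  The observation adds the
    group-scaled initial rise (additive, common to all regions) and i.i.d.
    Gaussian noise.
    """
    paradigm = paradigm or ParadigmSpec()
    seed = config.seed if seed is None else seed
    net = config.network
    mats = build_matrices(net, config.true_D, config.true_B)
    rho = spectral_radius(mats.M_output)
    if rho >= 1.0:
        raise ValueError(f"non-dissipative network: spectral radius of M_output {rho:.3f} >= 1")

    rng = np.random.default_rng(seed)
    t = paradigm.times
    study = SimulatedStudy(config=config, paradigm=paradigm)
    for group, n_p in config.n_participants.items():
        mult = config.rise_group_multiplier if group == "FM" else 1.0
        for p in range(n_p):
            pid = f"{group}{p:03d}"
            for run in range(config.n_runs):
                lat_seed = int(rng.integers(0, 2**31 - 1))
                latents = generate_latents(paradigm, config, lat_seed, rise_scale=mult)
                S_output, S_input = solve_forward(mats, latents)
                rise = config.rise_amplitude * mult * (1.0 - np.exp(-t / config.rise_tau))
                noise = rng.normal(0.0, config.noise_sd, size=S_input.shape)
                study.runs.append(
                    RunTimecourses(
                        values=S_input + rise + noise,
                        network_signal=S_input,
                        rise=rise,
                        latents=latents,
                        participant=pid,
                        group=group,
                        condition=paradigm.condition,
                        run=run,
                        TR=paradigm.TR,
                    )
                )
    return study


def make_subregion_timecourses(
    region_tc: np.ndarray,
    net: NetworkModel,
    k: int = 5,
    planted: dict | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> dict:
    """Per-region k x time sub-region matrices with a planted signal carrier.

    For each region, sub-region ``planted[region]`` (random under ``seed``
    when omitted) carries the region's network time course; the other k-1
    sub-regions are pure noise.  Returns (subregion_tcs, planted) where
    subregion_tcs maps region -> (k, T) array.
    """
    rng = np.random.default_rng(seed)
    region_tc = np.asarray(region_tc, float)
    T = region_tc.shape[1]
    if planted is None:
        planted = {r: int(rng.integers(k)) for r in net.regions}
    out = {}
    for i, r in enumerate(net.regions):
        m = rng.normal(0.0, noise_sd, size=(k, T))
        m[planted[r]] = region_tc[i]
        out[r] = m
    return out, planted


@dataclass
class VoxelDataset:
    """Voxel-level data for one region: voxel x time matrix, ground-truth
    sub-region labels (1..k) and arbitrary-unit spatial coordinates."""

    values: np.ndarray
    labels: np.ndarray
    coords: np.ndarray


def simulate_voxels(
    subregion_tc: np.ndarray,
    voxels_per_subregion: int = 10,
    within_sd: float = 0.1,
    seed: int = 0,
    baseline: float = 1000.0,
) -> VoxelDataset:
    """Voxel time series around each sub-region's time course.

    ``subregion_tc`` is (k, T) in % signal change.  Each voxel is raw-intensity
    like: ``baseline * (1 + (signal + noise)/100)``, so percent-signal-change
    preparation recovers the generating signal.  Labels are 1..k.
    """
    if voxels_per_subregion < 1:
        raise ValueError("voxels_per_subregion must be >= 1")
    rng = np.random.default_rng(seed)
    subregion_tc = np.asarray(subregion_tc, float)
    k, T = subregion_tc.shape
    n_vox = k * voxels_per_subregion
    values = np.empty((n_vox, T))
    labels = np.empty(n_vox, int)
    coords = np.empty((n_vox, 3))
    for j in range(k):
        sl = slice(j * voxels_per_subregion, (j + 1) * voxels_per_subregion)
        noise = rng.normal(0.0, within_sd, size=(voxels_per_subregion, T))
        values[sl] = baseline * (1.0 + (subregion_tc[j] + noise) / 100.0)
        labels[sl] = j + 1
        coords[sl] = rng.normal(loc=3.0 * j, scale=0.5, size=(voxels_per_subregion, 3))
    return VoxelDataset(values=values, labels=labels, coords=coords)


# ---------------------------------------------------------------------------
# pupillometry
# ---------------------------------------------------------------------------


@dataclass
class PupilGroupParams:
    """Group-level pupil generator parameters (pixel-area units).

    Defaults: HC-like baseline 1540, FM-like 1920; similar stimulation peak
    in both groups; white screen constricts, black screen dilates.
    """

    baseline_area: float = 1540.0
    stim_peak_area: float = 2400.0
    start_dilation: float = 200.0
    white_area: float = 900.0
    black_area: float = 2600.0
    blink_rate_hz: float = 0.0
    noise_sd: float = 30.0


PUPIL_DEFAULTS = {
    "HC": PupilGroupParams(baseline_area=1540.0),
    "FM": PupilGroupParams(baseline_area=1920.0),
}


@dataclass
class PupilTrace:
    """One trial's pupil-area trace at a constant sampling rate."""

    area: np.ndarray
    screen_state: np.ndarray  # per-sample {'white','black','task'}
    fs: float = 500.0
    participant: str = ""
    group: str = ""
    condition: str = "Pain"

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.area.size) / self.fs


def simulate_pupil(
    group_params: PupilGroupParams,
    n_trials: int,
    seed: int = 0,
    fs: float = 500.0,
    paradigm: ParadigmSpec | None = None,
    ref_duration: float = 2.0,
    group: str = "",
    n_participants: int = 1,
) -> list[PupilTrace]:
    """Simulate pupil-area trials with reference segments at both ends.

    Each trial: white then black reference screens (``ref_duration`` s each)
    before and after the task period, the task period following the paradigm
    timing (dilation at run start decaying to baseline, dilation toward the
    stimulation peak during the stimulation block), multiplicative trial
    variability, additive noise, and optional blink dropouts (area driven to
    near zero for ~100 ms).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    paradigm = paradigm or ParadigmSpec()
    rng = np.random.default_rng(seed)
    p = group_params

    n_ref = int(round(ref_duration * fs))
    n_task = int(round(paradigm.run_duration * fs))
    t_task = np.arange(n_task) / fs

    task_mean = np.full(n_task, p.baseline_area)
    task_mean += p.start_dilation * np.exp(-t_task / 20.0)
    if paradigm.condition == "Pain":
        in_stim = (t_task >= paradigm.stimulus_onset) & (t_task < paradigm.stimulus_offset)
        ramp = np.zeros(n_task)
        ramp[in_stim] = np.linspace(0.0, 1.0, int(in_stim.sum()))
        after = t_task >= paradigm.stimulus_offset
        ramp[after] = np.exp(-(t_task[after] - paradigm.stimulus_offset) / 15.0)
        task_mean = task_mean + (p.stim_peak_area - p.baseline_area) * ramp
    # baseline_area is the task-period average (the reported quantity);
    # recenter the dilation profile around it
    task_mean += p.baseline_area - task_mean.mean()

    state = np.array(
        ["white"] * n_ref + ["black"] * n_ref + ["task"] * n_task + ["white"] * n_ref + ["black"] * n_ref
    )
    traces = []
    for i in range(n_trials):
        gain = rng.normal(1.0, 0.03)
        segs = [
            np.full(n_ref, p.white_area),
            np.full(n_ref, p.black_area),
            task_mean * gain,
            np.full(n_ref, p.white_area),
            np.full(n_ref, p.black_area),
        ]
        area = np.concatenate(segs) + rng.normal(0.0, p.noise_sd, size=state.size)
        if p.blink_rate_hz > 0:
            total_s = state.size / fs
            n_blinks = rng.poisson(p.blink_rate_hz * total_s)
            for _ in range(n_blinks):
                start = rng.integers(0, state.size - int(0.1 * fs))
                area[start : start + int(0.1 * fs)] = rng.uniform(0.0, 10.0)
        traces.append(
            PupilTrace(
                area=area,
                screen_state=state.copy(),
                fs=fs,
                participant=f"{group}{i % max(n_participants, 1):03d}",
                group=group,
                condition=paradigm.condition,
            )
        )
    return traces
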