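"""Paradigm timing and latent temporal design.

The threat/safety paradigm: a 4.5-minute run; participants are informed at
the 1-minute mark whether a noxious stimulus will follow; in Pain runs, 10
heat contacts of 1.5 s with onsets every 3 s start at the 2-minute mark (a
30-s stimulation block); No-Pain runs carry the inform cue only.

Latent inputs are unobserved external drives.  Estimating them as completely
free time courses makes the signaling model non-identifiable — any invertible
remixing of the latents can be absorbed into the connection weightings — so
each latent is modeled inside its own temporal basis.  The basis groups are
paradigm-locked and disjoint across latents:

* an event group — hemodynamically convolved impulses at the inform cue and
  at stimulation onset and offset;
* a block group — convolved boxcars for the stimulation block and the
  anticipation (inform-to-onset) period (a sustained post-inform "safety"
  boxcar in No-Pain runs);
* a slow-arousal group — the saturating early-run component 1 - exp(-t/tau)
  plus low-order cosines.

With three latents each gets one group; with fewer, groups are shared
round-robin; with more, extra cosine bands are appended.  Disjoint bases pin
the latent mixing, and the fixed direct-input weighting of each latent's
target region pins scale and sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParadigmSpec",
    "make_paradigm",
    "hemodynamic_kernel",
    "build_latent_basis",
    "RISE_TAU_DEFAULT",
]

#: initial-rise time constant: 1 - exp(-t/tau) reaches ~95% saturation by 40 s
RISE_TAU_DEFAULT = 40.0 / 3.0


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing of one fMRI run of the threat/safety paradigm.

    Defaults give the 4.5-minute run with the inform cue at 60 s and, for
    Pain runs, a 30-s stimulation block (10 contacts, onsets every 3 s)
    starting at 120 s.
    """

    run_duration: float = 270.0
    TR: float = 2.0
    inform_time: float = 60.0
    stimulus_onset: float = 120.0
    n_contacts: int = 10
    contact_duration: float = 1.5
    onset_interval: float = 3.0
    condition: str = "Pain"

    def __post_init__(self):
        n = self.run_duration / self.TR
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(
                f"run_duration/TR = {n:.4f} is not a positive integer volume count"
            )
        if self.condition not in ("Pain", "NoPain"):
            raise ValueError(f"condition must be 'Pain' or 'NoPain', got {self.condition!r}")
        if self.condition == "Pain":
            if self.stimulus_onset + self.stimulation_duration > self.run_duration:
                raise ValueError("stimulation block exceeds the run duration")

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_duration / self.TR))

    @property
    def stimulation_duration(self) -> float:
        """Length of the stimulation block: n_contacts x onset_interval."""
        return self.n_contacts * self.onset_interval

    @property
    def stimulus_offset(self) -> float:
        return self.stimulus_onset + self.stimulation_duration

    @property
    def times(self) -> np.ndarray:
        """Volume acquisition times in seconds (0-based index x TR)."""
        return np.arange(self.n_volumes) * self.TR


def make_paradigm(condition: str = "Pain", **overrides) -> tuple[ParadigmSpec, np.ndarray]:
    """Build a paradigm and its per-volume stimulus indicator vector.

    The indicator is 1 while the thermode contacts the skin (Pain runs only),
    evaluated at each volume's acquisition time.
    """
    spec = ParadigmSpec(condition=condition, **overrides)
    t = spec.times
    indicator = np.zeros(spec.n_volumes)
    if condition == "Pain":
        for k in range(spec.n_contacts):
            onset = spec.stimulus_onset + k * spec.onset_interval
            indicator[(t >= onset) & (t < onset + spec.contact_duration)] = 1.0
    return spec, indicator


def hemodynamic_kernel(TR: float, width: float = 1.0, duration: float = 30.0) -> np.ndarray:
    """Gamma-shaped hemodynamic kernel sampled at TR, peaking ~5 s, unit peak.

    Shape parameter 6 with scale ``width`` (s); the conventional smooth BOLD
    impulse response without an undershoot term.
    """
    t = np.arange(0.0, duration, TR)
    a = 6.0
    with np.errstate(divide="ignore"):
        h = (t / width) ** (a - 1) * np.exp(-t / width)
    if h.max() > 0:
        h = h / h.max()
    return h


def _conv(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    return np.convolve(x, h)[: x.size]


def _standardize_cols(cols: list[np.ndarray]) -> np.ndarray:
    """Center each column and scale to unit standard deviation; drop
    numerically null columns."""
    out = []
    for c in cols:
        c = c - c.mean()
        sd = c.std()
        if sd > 1e-12:
            out.append(c / sd)
    return np.column_stack(out) if out else np.empty((cols[0].size, 0))


def basis_groups(
    paradigm: ParadigmSpec,
    n_groups: int = 3,
    kernel_width: float = 1.0,
    rise_tau: float = RISE_TAU_DEFAULT,
    n_cosines: int = 3,
) -> list[np.ndarray]:
    """The temporal basis groups (each a (T, p) column matrix).

    Groups: events, block, slow-arousal, then extra high-order cosine bands
    when more than three are requested.
    """
    t = paradigm.times
    n = paradigm.n_volumes
    h = hemodynamic_kernel(paradigm.TR, kernel_width)

    def stick(at: float) -> np.ndarray:
        s = np.zeros(n)
        i = int(np.searchsorted(t, at))
        if i < n:
            s[i] = 1.0
        return _conv(s, h)

    def boxcar(lo: float, hi: float) -> np.ndarray:
        return _conv(((t >= lo) & (t < hi)).astype(float), h)

    events = [stick(paradigm.inform_time)]
    if paradigm.condition == "Pain":
        events += [stick(paradigm.stimulus_onset), stick(paradigm.stimulus_offset)]
        block = [
            boxcar(paradigm.stimulus_onset, paradigm.stimulus_offset),
            boxcar(paradigm.inform_time, paradigm.stimulus_onset),
        ]
    else:
        block = [boxcar(paradigm.inform_time, paradigm.run_duration)]
    slow = [1.0 - np.exp(-t / rise_tau)] + [
        np.cos(np.pi * k * t / paradigm.run_duration) for k in range(1, n_cosines + 1)
    ]
    groups = [_standardize_cols(events), _standardize_cols(block), _standardize_cols(slow)]
    k = n_cosines + 1
    while len(groups) < n_groups:
        groups.append(
            _standardize_cols(
                [np.cos(np.pi * kk * t / paradigm.run_duration) for kk in (k, k + 1)]
            )
        )
        k += 2
    return groups[:n_groups] if n_groups <= 3 else groups


def _group_kinds(paradigm: ParadigmSpec, groups: list[np.ndarray], n_cosines: int) -> list:
    kinds = []
    for g, mat in enumerate(groups):
        if g == 0:
            kinds.append(["event"] * mat.shape[1])
        elif g == 1:
            kinds.append(["block"] * mat.shape[1])
        elif g == 2:
            kinds.append(["rise"] + ["cosine"] * (mat.shape[1] - 1))
        else:
            kinds.append(["cosine"] * mat.shape[1])
    return kinds


def build_latent_basis(
    paradigm: ParadigmSpec,
    n_latents: int,
    kernel_width: float = 1.0,
    rise_tau: float = RISE_TAU_DEFAULT,
    n_cosines: int = 3,
    return_kinds: bool = False,
):
    """Per-latent temporal bases: a list of (T, p_j) matrices.

    Basis groups are assigned round-robin so the latents' temporal subspaces
    are disjoint (the identifiability requirement); a single latent receives
    every group.  With ``return_kinds`` each basis comes with a per-column
    kind label in {event, block, rise, cosine}.
    """
    if n_latents < 1:
        return ([], []) if return_kinds else []
    n_groups = max(3, n_latents)
    groups = basis_groups(
        paradigm, n_groups=n_groups, kernel_width=kernel_width, rise_tau=rise_tau,
        n_cosines=n_cosines,
    )
    kinds = _group_kinds(paradigm, groups, n_cosines)
    per_latent: list[list[np.ndarray]] = [[] for _ in range(n_latents)]
    per_latent_kinds: list[list[str]] = [[] for _ in range(n_latents)]
    for g, mat in enumerate(groups):
        if mat.shape[1]:
            per_latent[g % n_latents].append(mat)
            per_latent_kinds[g % n_latents] += kinds[g]
    bases = [np.column_stack(mats) for mats in per_latent]
    if return_kinds:
        return bases, per_latent_kinds
    return bases
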