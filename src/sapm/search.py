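"""Greedy search over sub-region combinations.

Each region contributes one of its k (default 5) sub-region time courses to
the network fit; the search finds the combination with the least SAPM fit
error.  "Gradient descent" over this categorical grid is realized as greedy
coordinate descent: starting from a seeded random combination, regions are
swept in canonical network order, each region trying all k sub-region choices
with the others fixed and keeping the best (ties keep the incumbent); sweeps
repeat until one full sweep yields no improvement.  Multiple random starts
guard against local minima.

The winning combination is frozen and reused by all downstream analyses;
downstream code can verify a selection hash and refuse mismatched data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sapm.core import FitConfig, fit_sapm
from sapm.network import NetworkModel

__all__ = [
    "SubregionCombination",
    "SelectionMismatchError",
    "search_subregions",
    "freeze_combination",
    "load_frozen_combination",
    "verify_selection",
]


class SelectionMismatchError(ValueError):
    """Supplied sub-region selection differs from the frozen one."""


@dataclass
class SubregionCombination:
    """A chosen sub-region per region with its fit error and search history."""

    selection: dict  # region -> sub-region index (0-based)
    fit_error: float
    trajectory: list = field(default_factory=list)  # (iteration, error)
    network_name: str = ""

    def selection_hash(self) -> str:
        payload = json.dumps(
            {"network": self.network_name, "selection": dict(sorted(self.selection.items()))},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stack(subregion_tcs: dict, net: NetworkModel, selection: dict) -> np.ndarray:
    return np.asarray([subregion_tcs[r][selection[r]] for r in net.regions], float)


def search_subregions(
    subregion_tcs: dict,
    net: NetworkModel,
    fit_cfg: FitConfig | None = None,
    seed: int = 0,
    n_starts: int = 10,
    max_sweeps: int = 20,
    paradigm=None,
) -> SubregionCombination:
    """Greedy coordinate-descent search for the best sub-region combination.

    Parameters
    ----------
    subregion_tcs : mapping region -> (k, T) array of its sub-region time
        courses (k may differ per region but must be >= 1 for all).
    fit_cfg : SAPM fit configuration used to score each candidate (a full
        re-fit per candidate; results are cached by combination).
    seed, n_starts : random starting combinations; the best final error wins.
    """
    fit_cfg = fit_cfg or FitConfig(n_restarts=2)
    for r in net.regions:
        if r not in subregion_tcs or len(subregion_tcs[r]) < 1:
            raise ValueError(f"missing sub-region time courses for region {r}")
    k_of = {r: len(subregion_tcs[r]) for r in net.regions}
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}

    def score(selection: dict) -> float:
        key = tuple(selection[r] for r in net.regions)
        if key not in cache:
            cache[key] = fit_sapm(
                _stack(subregion_tcs, net, selection), net, fit_cfg, paradigm=paradigm
            ).fit_error
        return cache[key]

    best: SubregionCombination | None = None
    for _ in range(n_starts):
        selection = {r: int(rng.integers(k_of[r])) for r in net.regions}
        err = score(selection)
        traj = [(0, err)]
        it = 0
        for _sweep in range(max_sweeps):
            improved = False
            for r in net.regions:
                incumbent = selection[r]
                best_j, best_err = incumbent, err
                for j in range(k_of[r]):
                    if j == incumbent:
                        continue
                    cand = dict(selection, **{r: j})
                    e = score(cand)
                    if e < best_err:  # strict: ties keep the incumbent
                        best_j, best_err = j, e
                if best_j != incumbent:
                    selection[r] = best_j
                    err = best_err
                    improved = True
                it += 1
                traj.append((it, err))
            if not improved:
                break
        if best is None or err < best.fit_error:
            best = SubregionCombination(
                selection=dict(selection), fit_error=err, trajectory=traj, network_name=net.name
            )
    return best


def freeze_combination(comb: SubregionCombination, path: str | Path) -> Path:
    """Serialize the combination (with its hash) for downstream reuse."""
    path = Path(path)
    payload = {
        "network": comb.network_name,
        "selection": comb.selection,
        "fit_error": comb.fit_error,
        "hash": comb.selection_hash(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_frozen_combination(path: str | Path) -> SubregionCombination:
    d = json.loads(Path(path).read_text())
    comb = SubregionCombination(
        selection={r: int(j) for r, j in d["selection"].items()},
        fit_error=float(d["fit_error"]),
        network_name=d.get("network", ""),
    )
    if comb.selection_hash() != d["hash"]:
        raise SelectionMismatchError(
            f"frozen selection hash {d['hash']} does not match recomputed "
            f"{comb.selection_hash()}"
        )
    return comb


def verify_selection(
    frozen: SubregionCombination, supplied: dict, override: bool = False
) -> None:
    """Refuse a supplied selection that differs from the frozen one.

    All analyses after the search reuse the frozen combination for
    consistency (brain and brainstem/cord analyses share frozen choices for
    their common regions); pass ``override=True`` to bypass deliberately.
    """
    if override:
        return
    common = set(frozen.selection) & set(supplied)
    diffs = {r: (frozen.selection[r], supplied[r]) for r in common if frozen.selection[r] != supplied[r]}
    if diffs:
        raise SelectionMismatchError(
            f"supplied selection differs from frozen combination at: {diffs}"
        )
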