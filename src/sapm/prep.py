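"""Time-course preparation and 5-sub-region voxel clustering.

Preparation follows the acquisition conventions: the first volumes of each
run carry variable T1-weighting and are replaced (not dropped, to preserve
time-since-run-start information) with the first subsequent value — 3 volumes
for brain data, 2 for brainstem/cord data.  Raw intensities are converted to
percent signal change about the within-run mean.  Each region's voxels are
partitioned into k = 5 sub-regions by k-means on standardized voxel time
courses; "approximately equal volume" is monitored by a balance warning
rather than enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "ClusterBalanceWarning",
    "mask_initial_volumes",
    "to_percent_signal_change",
    "cluster_region",
    "extract_subregion_timecourses",
    "average_runs",
    "MASK_DEFAULTS",
]

#: initial volumes replaced per acquisition type
MASK_DEFAULTS = {"brain": 3, "brainstem_cord": 2}


class ClusterBalanceWarning(UserWarning):
    """Sub-region sizes are strongly unbalanced (max/min > 3)."""


def mask_initial_volumes(series: np.ndarray, n_replace: int) -> np.ndarray:
    """Replace the first ``n_replace`` time points with the value at index
    ``n_replace`` (0-based); length unchanged.  Time is the last axis."""
    series = np.asarray(series, float)
    n_time = series.shape[-1]
    if n_replace >= n_time:
        raise ValueError(f"n_replace={n_replace} >= series length {n_time}")
    out = series.copy()
    if n_replace > 0:
        out[..., :n_replace] = series[..., n_replace : n_replace + 1]
    return out


def to_percent_signal_change(raw: np.ndarray) -> np.ndarray:
    """100 * (x - mean(x)) / mean(x) per series (time on the last axis).

    The run mean must be positive (raw MRI intensity); zero or negative means
    indicate invalid input and raise.
    """
    raw = np.asarray(raw, float)
    mean = raw.mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("run mean must be positive to form percent signal change")
    return 100.0 * (raw - mean) / mean


@dataclass
class ClusterAssignment:
    """Voxel -> sub-region labels (1..k) for one region."""

    labels: np.ndarray
    k: int
    counts: np.ndarray
    balanced: bool

    def voxels_in(self, subregion: int) -> np.ndarray:
        return np.flatnonzero(self.labels == subregion)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance, so the assignment
    is invariant to k-means' internal label permutation."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    nxt = 1
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def cluster_region(
    voxel_matrix: np.ndarray, k: int = 5, seed: int = 0, n_restarts: int = 10
) -> ClusterAssignment:
    """k-means partition of a region's voxels on standardized time courses.

    Deterministic under ``seed``; emits :class:`ClusterBalanceWarning` when
    max/min sub-region size exceeds 3.
    """
    voxel_matrix = np.asarray(voxel_matrix, float)
    n_vox = voxel_matrix.shape[0]
    if n_vox < k:
        raise ValueError(f"need at least k={k} voxels, got {n_vox}")
    z = stats.zscore(voxel_matrix, axis=1)
    z = np.nan_to_num(z)  # constant voxels -> zero vector
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = _canonical_labels(km.fit_predict(z))
    counts = np.bincount(labels, minlength=k + 1)[1:]
    balanced = counts.min() > 0 and counts.max() / max(counts.min(), 1) <= 3
    if not balanced:
        warnings.warn(
            f"sub-region sizes unbalanced: {counts.tolist()}", ClusterBalanceWarning, stacklevel=2
        )
    return ClusterAssignment(labels=labels, k=k, counts=counts, balanced=balanced)


def extract_subregion_timecourses(
    voxels: np.ndarray, assignment: ClusterAssignment
) -> np.ndarray:
    """Mean raw time course per sub-region, then percent signal change.

    Returns a (k, T) matrix ordered by sub-region label 1..k.
    """
    voxels = np.asarray(voxels, float)
    out = np.empty((assignment.k, voxels.shape[1]))
    for j in range(1, assignment.k + 1):
        idx = assignment.voxels_in(j)
        if idx.size == 0:
            raise ValueError(f"sub-region {j} is empty")
        out[j - 1] = voxels[idx].mean(axis=0)
    return to_percent_signal_change(out)


def average_runs(runs: list) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard error across runs/participants.

    ``runs`` is a sequence of equally shaped arrays (time on the last axis).
    A single run returns itself with zero sem.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    arrs = [np.asarray(r, float) for r in runs]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"run shape mismatch: {a.shape} vs {shape}")
    stacked = np.stack(arrs)
    mean = stacked.mean(axis=0)
    if len(arrs) == 1:
        sem = np.zeros_like(mean)
    else:
        sem = stats.sem(stacked, axis=0, ddof=1)
    return mean, sem
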