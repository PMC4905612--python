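"""Clustering of features that are in phase for a significant period.

Once a period P is significant, every feature gets a phase coordinate
(position mod P).  Features whose phases agree — "in-phase" features — may
be spatially co-localised when the chromosome folds with that period, so we
cluster the phases with DBSCAN under the circular metric

    dist(phi1, phi2) = min(|phi1 - phi2|, P - |phi1 - phi2|),

and score each feature's individual contribution to the period's
significance (the positional score).  The clustergram table pairs both.

The DBSCAN neighbourhood radius interpolates geometrically between the
user's proximity threshold d and the period itself:

    eps = P**(1 - e) * d**e,   e in (0, 1]  (the clustering exponent),

so e = 1 recovers the plain proximity threshold while e -> 0 widens the
radius toward P (everything merges), giving a single sensitivity dial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .features import FeatureSet
from .periodicity import phase_transform, periodicity_score

__all__ = [
    "NOISE_LABEL",
    "ClusterParams",
    "cluster_phases",
    "positional_scores",
    "clustergram_table",
    "build_clustergram",
]

NOISE_LABEL = 0  # clusters are numbered 1..k; noise carries the reserved 0


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the phase clustering for one period."""

    period: float
    proximity: float
    clustering_exponent: float = 0.5
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.clustering_exponent <= 1.0):
            raise ValueError(
                f"clustering exponent must be in (0, 1], got {self.clustering_exponent}"
            )
        if self.period <= 0 or self.proximity <= 0:
            raise ValueError("period and proximity must be positive")
        if self.min_cluster_size < 2:
            raise ValueError(f"min_cluster_size must be >= 2, got {self.min_cluster_size}")

    @property
    def eps(self) -> float:
        """DBSCAN radius: geometric interpolation between proximity and period."""
        e = self.clustering_exponent
        return self.period ** (1.0 - e) * self.proximity**e


def _circular_distance_matrix(phases: np.ndarray, period: float) -> np.ndarray:
    diff = np.abs(phases[:, None] - phases[None, :])
    return np.minimum(diff, period - diff)


def cluster_phases(fs: FeatureSet, params: ClusterParams) -> pd.DataFrame:
    """DBSCAN on phase coordinates under the circular wrap-around metric.

    Returns one row per feature (name, position, phase, cluster); cluster
    labels are contiguous from 1 in order of first appearance along the
    phase axis, noise points carry :data:`NOISE_LABEL`.  Points are visited
    in sorted phase order so labelling is deterministic.
    """
    n = len(fs)
    if n < params.min_cluster_size:
        raise ValueError(
            f"{n} features < min_cluster_size {params.min_cluster_size}"
        )
    phases = phase_transform(fs.positions, params.period)
    order = np.lexsort((fs.positions, phases))  # phase-major, deterministic
    sorted_phases = phases[order]
    dm = _circular_distance_matrix(sorted_phases, params.period)
    raw = DBSCAN(
        eps=params.eps, min_samples=params.min_cluster_size, metric="precomputed"
    ).fit_predict(dm)
    # relabel to 1..k by first appearance in phase order; sklearn noise -1 -> 0
    mapping: dict[int, int] = {}
    labels_sorted = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab == -1:
            labels_sorted[i] = NOISE_LABEL
        else:
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            labels_sorted[i] = mapping[lab]
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return pd.DataFrame(
        dict(
            name=fs.names,
            position=fs.positions,
            phase=phases,
            cluster=labels,
        )
    )


def positional_scores(fs: FeatureSet | np.ndarray, period: float) -> np.ndarray:
    """Each feature's contribution to the period's significance, in [0, 1].

    The raw contribution is leave-one-out on the periodicity score,
    c_i = S(all) - S(all without i): features sitting inside a phase
    cluster prop the score up (positive c_i), isolated features drag it
    down.  Contributions are min-max normalised across the set; if all are
    equal (e.g. perfectly uniform contributions) every score is 1.
    """
    positions = fs.positions if isinstance(fs, FeatureSet) else np.asarray(fs, float)
    n = positions.size
    if n < 3:
        raise ValueError(f"positional scores need >= 3 features, got {n}")
    angles = 2.0 * np.pi * (np.asarray(positions, float) % period) / period
    z = np.exp(1j * angles)
    total = z.sum()
    s_all = abs(total) ** 2 / n
    s_loo = np.abs(total - z) ** 2 / (n - 1)
    contrib = s_all - s_loo
    span = contrib.max() - contrib.min()
    if span < 1e-12:
        return np.ones(n)
    return (contrib - contrib.min()) / span


def build_clustergram(fs: FeatureSet, params: ClusterParams) -> pd.DataFrame:
    """Cluster phases and attach positional scores in one call."""
    rows = cluster_phases(fs, params)
    rows["positional_score"] = positional_scores(fs, params.period)
    return clustergram_table(rows, params)


def clustergram_table(rows: pd.DataFrame, params: ClusterParams) -> pd.DataFrame:
    """Plot-ready clustergram: one feature per row, sorted by phase."""
    required = {"name", "position", "phase", "cluster", "positional_score"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"clustergram rows missing columns: {sorted(missing)}")
    out = rows.sort_values(["phase", "position"], kind="mergesort").reset_index(drop=True)
    return out
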