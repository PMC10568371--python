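"""STOCSY coupling of spatial clusters.

Statistical total correlation spectroscopy exploits the fact that all
resonances of one molecule co-vary with its concentration across samples.
Here it operates on SPA clusters rather than raw datapoints: each cluster
is reduced to a per-sample representative intensity (mean of its local
maxima), clusters are correlated across samples, and clusters connected by
correlations at or above a threshold (default 0.8) are grouped into
connected components — putative same-molecule groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dataset import SpectrumSet
from .spa import ClusterSet

__all__ = [
    "ClusterIntensityMatrix",
    "StocsyGroupSet",
    "cluster_intensities",
    "stocsy_correlate",
    "group_clusters",
    "calibrate_threshold",
]

DEFAULT_STOCSY_THRESHOLD = 0.8


class CalibrationError(RuntimeError):
    """Reference clusters never co-group at any candidate threshold."""


@dataclass
class ClusterIntensityMatrix:
    """Per-sample representative intensities of spatial clusters.

    ``values`` is n_samples x n_clusters; entry (i, c) is the mean of the
    local-maxima peak intensities of sample i inside cluster c (or the
    cluster maximum when the segment has no interior local maximum).
    """

    values: np.ndarray
    cluster_ids: list[int]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.cluster_ids)):
            raise ValueError("intensity matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cluster intensities must be finite")

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]


@dataclass
class StocsyGroupSet:
    """Partition of clusters into highly correlated groups.

    ``groups`` maps group id -> sorted list of member cluster ids; groups
    are the connected components of the graph with an edge wherever
    ``correlation >= threshold``, ordered by their smallest member id.
    """

    correlation: np.ndarray
    threshold: float
    groups: dict[int, list[int]]
    cluster_ids: list[int]

    @property
    def singleton_flags(self) -> dict[int, bool]:
        return {g: len(m) == 1 for g, m in self.groups.items()}

    def group_of(self, cluster_id: int) -> int:
        for g, members in self.groups.items():
            if cluster_id in members:
                return g
        raise KeyError(f"cluster {cluster_id} not in any group")


def _segment_peak_values(x: np.ndarray) -> np.ndarray:
    """Intensities of interior local maxima of a segment (plateau-aware);
    falls back to the segment maximum when no interior maximum exists."""
    peaks, _ = find_peaks(x)
    if peaks.size == 0:
        return np.array([x.max()])
    return x[peaks]


def cluster_intensities(spectra: SpectrumSet, clusters: ClusterSet
                        ) -> ClusterIntensityMatrix:
    """Representative intensity of every cluster in every sample.

    Local maxima use strict two-neighbour comparison (plateau apexes take
    the plateau midpoint); a monotone segment falls back to its maximum.
    """
    p = spectra.n_points
    for c in clusters:
        if c.start_index < 0 or c.end_index >= p:
            raise ValueError(f"cluster {c} lies outside the ppm grid")
    values = np.empty((spectra.n_samples, len(clusters)))
    for j, c in enumerate(clusters):
        seg = spectra.intensities[:, c.start_index:c.end_index + 1]
        for i in range(spectra.n_samples):
            values[i, j] = _segment_peak_values(seg[i]).mean()
    return ClusterIntensityMatrix(values, list(range(len(clusters))),
                                  list(spectra.sample_ids))


def stocsy_correlate(intensities: ClusterIntensityMatrix) -> np.ndarray:
    """Pearson correlation matrix of cluster representative intensities.

    Zero-variance clusters get zero off-diagonal correlations (with a
    warning) and a unit diagonal.
    """
    X = intensities.values
    if X.shape[0] < 3:
        raise ValueError("STOCSY correlation needs at least 3 samples")
    sd = X.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        warnings.warn(f"zero-variance cluster columns {flat.tolist()}: "
                      "correlations set to 0", RuntimeWarning)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z[:, flat] = 0.0
    R = (Z.T @ Z) / X.shape[0]
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def group_clusters(correlation: np.ndarray,
                   threshold: float = DEFAULT_STOCSY_THRESHOLD,
                   cluster_ids: list[int] | None = None) -> StocsyGroupSet:
    """Connected components of the thresholded correlation graph.

    An edge joins clusters whose correlation is >= threshold (signed r, not
    |r|: under a concentration-driven model, same-molecule clusters co-vary
    positively). Groups are numbered by their smallest member cluster id.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    c = np.asarray(correlation, dtype=float)
    m = c.shape[0]
    ids = cluster_ids if cluster_ids is not None else list(range(m))
    adj = csr_matrix((c >= threshold).astype(int))
    _, labels = connected_components(adj, directed=False)
    comp: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        comp.setdefault(lab, []).append(ids[idx])
    ordered = sorted(comp.values(), key=min)
    groups = {g: sorted(members) for g, members in enumerate(ordered)}
    return StocsyGroupSet(c, threshold, groups, list(ids))


def calibrate_threshold(intensities: ClusterIntensityMatrix,
                        reference_cluster_ids: list[int],
                        grid: np.ndarray | None = None) -> float:
    """Largest grid threshold at which all reference clusters co-group.

    The reference clusters come from an internal standard (e.g. DSS) or a
    known abundant metabolite resonating at several positions; the highest
    threshold that still keeps all of them in one STOCSY group is the
    calibrated grouping threshold.
    """
    refs = list(reference_cluster_ids)
    if len(refs) < 2:
        raise ValueError("calibration needs at least 2 reference cluster ids")
    grid = np.round(np.arange(0.95, 0.299, -0.05), 2) if grid is None \
        else np.asarray(grid, dtype=float)
    R = stocsy_correlate(intensities)
    for t in grid:
        gs = group_clusters(R, float(t), intensities.cluster_ids)
        g0 = gs.group_of(refs[0])
        if all(gs.group_of(r) == g0 for r in refs[1:]):
            return float(t)
    pos = {cid: i for i, cid in enumerate(intensities.cluster_ids)}
    pairs = {(a, b): float(R[pos[a], pos[b]])
             for i, a in enumerate(refs) for b in refs[i + 1:]}
    raise CalibrationError(
        f"reference clusters never co-group down to threshold {grid[-1]}; "
        f"pairwise correlations: {pairs}")
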