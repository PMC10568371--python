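"""Statistical Recoupling of Variables (SRV) baseline clustering.

SRV scans the landscape L_j = sqrt(var(x_j) * var(x_{j+1})) over adjacent
spectral variables (the covariance/correlation ratio), places cluster
boundaries at its local minima, discards clusters with fewer than
``min_cluster_size`` variables (default 10), and finally chains
neighbouring clusters whose representative intensities correlate above
``supercluster_r`` (default 0.9) into super-clusters of at most
``supercluster_cap`` members (default 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectrumSet
from .spa import ClusterSet, SpatialCluster

__all__ = ["SRVParams", "srv_landscape", "srv_cluster", "srv_superclusters"]


@dataclass
class SRVParams:
    min_cluster_size: int = 10
    supercluster_r: float = 0.9
    supercluster_cap: int = 3


def srv_landscape(spectra: SpectrumSet) -> np.ndarray:
    """L_j = sqrt(var(x_j) var(x_{j+1})) for j = 0..p-2 (population variance)."""
    if spectra.n_points < 3:
        raise ValueError("SRV landscape needs at least 3 datapoints")
    v = spectra.intensities.var(axis=0)
    return np.sqrt(v[:-1] * v[1:])


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; plateau minima take the midpoint."""
    mins = []
    m = values.size
    i = 1
    while i < m - 1:
        j = i
        while j + 1 < m and values[j + 1] == values[i]:
            j += 1
        if values[i] < values[i - 1] and j + 1 < m and values[i] < values[j + 1]:
            mins.append((i + j) // 2)
        i = j + 1
    return np.asarray(mins, dtype=int)


def srv_cluster(spectra: SpectrumSet, params: SRVParams | None = None
                ) -> ClusterSet:
    """Segments between successive local minima of the SRV landscape.

    A flat landscape (no minima) yields one cluster spanning the spectrum.
    Segments shorter than ``min_cluster_size`` variables are discarded.
    """
    params = params or SRVParams()
    if spectra.n_samples < 3:
        raise ValueError("SRV needs at least 3 samples")
    L = srv_landscape(spectra)
    cuts = _local_minima(L)  # a minimum at L[j] separates columns j and j+1
    ppm = spectra.ppm_axis
    bounds = np.concatenate(([0], cuts + 1, [spectra.n_points]))
    clusters = []
    for s, e in zip(bounds[:-1], bounds[1:] - 1):
        if e - s + 1 >= params.min_cluster_size:
            clusters.append(SpatialCluster(int(s), int(e),
                                           float(ppm[s]), float(ppm[e])))
    return ClusterSet(clusters, ppm)


def srv_superclusters(clusters: ClusterSet, spectra: SpectrumSet,
                      r: float = 0.9, cap: int = 3) -> np.ndarray:
    """Greedy left-to-right chaining of neighbouring clusters.

    The representative intensity of a cluster is the per-sample mean over
    its member variables. Walking the (sorted) clusters, a cluster joins
    the current chain when its representative correlates > r with the
    previous cluster's and the chain holds fewer than ``cap`` members.
    Returns a per-cluster super-cluster label array.
    """
    m = len(clusters)
    labels = np.zeros(m, dtype=int)
    if m == 0:
        return labels
    reps = np.stack([spectra.intensities[:, c.start_index:c.end_index + 1].mean(axis=1)
                     for c in clusters], axis=1)
    current, size = 0, 1
    for j in range(1, m):
        a, b = reps[:, j - 1], reps[:, j]
        if a.std() > 0 and b.std() > 0:
            corr = float(np.corrcoef(a, b)[0, 1])
        else:
            corr = 0.0
        if corr > r and size < cap:
            size += 1
        else:
            current += 1
            size = 1
        labels[j] = current
    return labels
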