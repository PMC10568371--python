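"""Spatial clustering of NMR spectral variables (SPA).

SPA scans a moving window of ``k`` consecutive spectral variables and
records, at each window start ``j``, the average of all k(k-1)/2 pairwise
Pearson correlations (across samples) among the window's columns — the
*correlation landscape*. The landscape is kernel-smoothed (Epanechnikov or
tricube), thresholded at a correlation level ``lambda``, and maximal
contiguous runs above the threshold become spatial clusters: stretches of
datapoints likely to belong to one structural unit of one metabolite.

Both tuning parameters are selected from the data itself:

* the window size ``k`` is the smallest lag at which the partial
  autocorrelation function (PACF) of the spectrum falls inside its
  confidence band — beyond that lag, neighbouring datapoints no longer
  carry extra serial dependence;
* the threshold ``lambda`` is chosen by *prediction strength*: samples are
  split into halves, each half is clustered independently, and the median
  fraction of within-cluster variable pairs of one half that are
  co-clustered in the other half measures stability. The chosen lambda is
  the smallest grid value whose mean strength over folds lies within one
  standard error of the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import SpectrumSet

__all__ = [
    "CorrelationLandscape",
    "SpatialCluster",
    "ClusterSet",
    "ThresholdSearchResult",
    "select_window_size",
    "correlation_landscape",
    "smooth_landscape",
    "prediction_strength",
    "select_threshold",
    "extract_clusters",
    "co_membership_strength",
    "spa_cluster",
    "KERNELS",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.30, 0.951, 0.05), 2)


class NoStableClusteringError(RuntimeError):
    """Prediction strength is zero on the whole threshold grid."""


# ---------------------------------------------------------------------------
# landscape


@dataclass
class CorrelationLandscape:
    """Moving-window correlation landscape over the ppm grid.

    ``values[j]`` is the average pairwise Pearson correlation among columns
    ``j .. j+k-1`` (NaN at the trailing ``k-1`` positions, where no full
    window fits). ``smoothed`` marks whether a kernel has been applied.
    """

    values: np.ndarray
    window_size: int
    ppm_axis: np.ndarray
    kernel: str = "none"
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.values.size != self.ppm_axis.size:
            raise ValueError("landscape length must match the ppm grid")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class SpatialCluster:
    """Contiguous run of ppm-grid indices, inclusive on both ends."""

    start_index: int
    end_index: int
    start_ppm: float
    end_ppm: float

    @property
    def member_count(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.end_index + 1)


@dataclass
class ClusterSet:
    """Disjoint, sorted spatial clusters on a shared ppm grid."""

    clusters: list[SpatialCluster]
    ppm_axis: np.ndarray

    def __post_init__(self) -> None:
        prev_end = -1
        for c in self.clusters:
            if c.start_index > c.end_index:
                raise ValueError("cluster start must be <= end")
            if c.start_index <= prev_end:
                raise ValueError("clusters must be disjoint and sorted")
            prev_end = c.end_index

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def covered_indices(self) -> np.ndarray:
        if not self.clusters:
            return np.empty(0, dtype=int)
        return np.concatenate([c.indices for c in self.clusters])

    def labels(self, p: int) -> np.ndarray:
        """Per-variable cluster label, -1 for unclustered positions."""
        lab = np.full(p, -1, dtype=int)
        for i, c in enumerate(self.clusters):
            lab[c.start_index:c.end_index + 1] = i
        return lab


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored columns (population SD); zero-variance columns zeroed out."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    nonzero = sd > 0
    Z = np.where(nonzero[None, :], Xc / np.where(nonzero, sd, 1.0)[None, :], 0.0)
    return Z, nonzero


def correlation_landscape(spectra: SpectrumSet, k: int) -> CorrelationLandscape:
    """Average pairwise Pearson correlation in each window of ``k`` columns.

    Any pair involving a zero-variance column (e.g. a baseline-zeroed
    stretch) contributes 0 to the window average, so flat baseline reads as
    "no dependence" rather than NaN. Computed in O(k p) via lagged
    correlation series and sliding-window cumulative sums.
    """
    n, p = spectra.intensities.shape
    if n < 3:
        raise ValueError("correlation landscape needs n >= 3 samples")
    if k < 2:
        raise ValueError("window size k must be >= 2")
    if k > p:
        raise ValueError("window size k cannot exceed the number of datapoints")
    Z, _ = _standardize_columns(spectra.intensities)
    n_windows = p - k + 1
    sums = np.zeros(n_windows)
    for d in range(1, k):
        # r[j] = Pearson correlation of columns j and j+d (0 if either flat)
        r = (Z[:, :-d] * Z[:, d:]).mean(axis=0)
        cs = np.concatenate(([0.0], np.cumsum(r)))
        # window starting at j contains pairs (j+s, j+s+d), s = 0..k-1-d
        sums += cs[k - d:k - d + n_windows] - cs[:n_windows]
    values = np.full(p, np.nan)
    values[:n_windows] = sums / (k * (k - 1) / 2.0)
    return CorrelationLandscape(values, k, spectra.ppm_axis.copy())


# ---------------------------------------------------------------------------
# kernel smoothing

def _epanechnikov(t: np.ndarray) -> np.ndarray:
    t = np.abs(t)
    return np.where(t <= 1.0, 0.75 * (1.0 - t**2), 0.0)


def _tricube(t: np.ndarray) -> np.ndarray:
    t = np.abs(t)
    return np.where(t <= 1.0, (1.0 - t**3) ** 3, 0.0)


KERNELS = {"epanechnikov": _epanechnikov, "tricube": _tricube}


def smooth_landscape(landscape: CorrelationLandscape, kernel: str = "tricube",
                     bandwidth: int | None = None) -> CorrelationLandscape:
    """Kernel-weighted moving average of the landscape.

    ``t`` is |offset|/bandwidth; weights are renormalized to sum to 1 over
    the neighbours actually available (edges, undefined positions), so a
    constant landscape is left unchanged. Undefined (NaN) positions remain
    undefined. The default bandwidth is half the window size (floored at 2):
    the smoother's support then stays inside one structural unit, so genuine
    correlation dips between adjacent units narrower than the window are
    stabilized but not erased.
    """
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    bw = int(bandwidth if bandwidth is not None
             else max(2, landscape.window_size // 2))
    if bw < 1:
        raise ValueError("bandwidth must be >= 1")
    offsets = np.arange(-bw, bw + 1)
    w = KERNELS[kernel](offsets / bw)
    vals = landscape.values
    mask = ~np.isnan(vals)
    filled = np.where(mask, vals, 0.0)
    num = np.convolve(filled, w[::-1], mode="same")
    den = np.convolve(mask.astype(float), w[::-1], mode="same")
    out = np.full_like(vals, np.nan)
    ok = mask & (den > 0)
    out[ok] = num[ok] / den[ok]
    return CorrelationLandscape(out, landscape.window_size,
                                landscape.ppm_axis, kernel, smoothed=True)


# ---------------------------------------------------------------------------
# window-size selection (PACF)

def _pacf_first_inside(x: np.ndarray, alpha: float, max_lag: int) -> int | None:
    """Smallest lag whose PACF lies inside the +/- z/sqrt(len) band."""
    from statsmodels.tsa.stattools import pacf

    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return 1  # flat series: no serial dependence at any lag
    nlags = min(max_lag, x.size // 2 - 1)
    vals = pacf(x, nlags=nlags, method="ywm")
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    band = z / np.sqrt(x.size)
    for lag in range(1, nlags + 1):
        if abs(vals[lag]) < band:
            return lag
    return None


def select_window_size(spectra: SpectrumSet, alpha: float = 0.95,
                       max_lag: int = 50) -> int:
    """Window size from the PACF cut-off of the spectra.

    For the mean spectrum and for each individual spectrum, the candidate
    window is the smallest lag at which the PACF falls inside the
    ``alpha``-level confidence band; the returned k is the median of those
    candidates, floored at 2. If a series' PACF never enters the band up to
    ``max_lag``, that series contributes ``max_lag`` and a warning is issued.
    """
    if spectra.n_points < 50:
        raise ValueError("PACF window selection needs at least 50 datapoints")
    series = [spectra.mean_spectrum()] + [row for row in spectra.intensities]
    ks = []
    for x in series:
        k = _pacf_first_inside(x, alpha, max_lag)
        if k is None:
            warnings.warn(
                f"PACF did not enter the confidence band up to lag {max_lag}; "
                "using max_lag as the window size", RuntimeWarning)
            k = max_lag
        ks.append(k)
    return max(2, int(np.median(ks)))


# ---------------------------------------------------------------------------
# cluster extraction

def extract_clusters(landscape: CorrelationLandscape, lam: float,
                     min_size: int | None = None) -> ClusterSet:
    """Maximal contiguous runs of the smoothed landscape >= lambda.

    Runs shorter than ``min_size`` datapoints (default: the window size, the
    natural resolution floor) are discarded. Undefined positions never
    belong to a cluster.
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    ms = int(min_size if min_size is not None else landscape.window_size)
    above = np.nan_to_num(landscape.values, nan=-np.inf) >= lam
    ppm = landscape.ppm_axis
    clusters: list[SpatialCluster] = []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    for s, e in zip(starts, ends):
        if e - s + 1 >= ms:
            clusters.append(SpatialCluster(int(s), int(e),
                                           float(ppm[s]), float(ppm[e])))
    return ClusterSet(clusters, ppm)


# ---------------------------------------------------------------------------
# prediction strength

@dataclass
class ThresholdSearchResult:
    lambda_grid: np.ndarray
    mean_strength: np.ndarray
    se_strength: np.ndarray
    chosen_lambda: float
    window_size: int = 0
    kernel: str = "tricube"


def _half_landscapes(spectra: SpectrumSet, k: int, kernel: str, n_folds: int,
                     rng: np.random.Generator, bandwidth: int | None):
    """Per fold: smoothed landscapes of two random equal halves of samples."""
    n = spectra.n_samples
    if n < 4:
        raise ValueError("prediction strength needs n >= 4 samples")
    pairs = []
    for _ in range(n_folds):
        perm = rng.permutation(n)
        half = n // 2
        out = []
        for idx in (perm[:half], perm[half:2 * half]):
            sub = SpectrumSet(spectra.ppm_axis, spectra.intensities[idx],
                              [spectra.sample_ids[i] for i in idx])
            out.append(smooth_landscape(correlation_landscape(sub, k), kernel))
        pairs.append(tuple(out))
    return pairs


def co_membership_strength(scored: ClusterSet, other: ClusterSet, p: int) -> float:
    """Median over scored clusters (size >= 2) of the fraction of their
    within-cluster variable pairs co-clustered under ``other``."""
    other_labels = other.labels(p)
    fracs = []
    for c in scored:
        m = c.member_count
        if m < 2:
            continue  # pair set empty; skipped from the median
        labs = other_labels[c.start_index:c.end_index + 1]
        counts = np.bincount(labs[labs >= 0]) if (labs >= 0).any() else np.empty(0, int)
        co_pairs = float(np.sum(counts * (counts - 1)))
        fracs.append(co_pairs / (m * (m - 1)))
    if not fracs:
        return 0.0
    return float(np.median(fracs))


def _pd_for_pair(pair, lam: float, min_size: int | None) -> float:
    cs1 = extract_clusters(pair[0], lam, min_size)
    cs2 = extract_clusters(pair[1], lam, min_size)
    p = pair[0].values.size
    if len(cs1) == 0 or len(cs2) == 0:
        return 0.0
    # symmetrized: score each half's clusters by the other half's memberships
    return 0.5 * (co_membership_strength(cs1, cs2, p)
                  + co_membership_strength(cs2, cs1, p))


def prediction_strength(spectra: SpectrumSet, lam: float, k: int,
                        kernel: str = "tricube", n_folds: int = 5,
                        seed: int | None = 0,
                        min_size: int | None = None,
                        bandwidth: int | None = None) -> tuple[float, float]:
    """Mean and standard error of the prediction strength over random folds.

    Each fold splits the samples into two equal halves, clusters each half
    independently at threshold ``lam``, and scores the stability of the
    co-membership of spectral variables between the halves.
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pairs = _half_landscapes(spectra, k, kernel, n_folds, rng, bandwidth)
    pds = np.array([_pd_for_pair(pair, lam, min_size) for pair in pairs])
    se = float(pds.std(ddof=1) / np.sqrt(n_folds)) if n_folds > 1 else 0.0
    return float(pds.mean()), se


def select_threshold(spectra: SpectrumSet, lambda_grid=None, k: int = 7,
                     kernel: str = "tricube", n_folds: int = 5,
                     seed: int | None = 0,
                     min_size: int | None = None,
                     bandwidth: int | None = None) -> ThresholdSearchResult:
    """One-standard-error choice of the landscape threshold.

    The chosen lambda is the smallest grid value whose mean prediction
    strength lies within one standard error of the maximum mean strength
    (ties broken toward the smallest lambda). Raises
    :class:`NoStableClusteringError` when every grid value scores zero.
    """
    grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid,
                      dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("lambda_grid must be ascending and inside (0, 1)")
    rng = np.random.default_rng(seed)
    pairs = _half_landscapes(spectra, k, kernel, n_folds, rng, bandwidth)
    pds = np.array([[_pd_for_pair(pair, lam, min_size) for pair in pairs]
                    for lam in grid])  # (grid, folds)
    means = pds.mean(axis=1)
    ses = pds.std(axis=1, ddof=1) / np.sqrt(n_folds) if n_folds > 1 \
        else np.zeros(grid.size)
    if np.all(means == 0):
        raise NoStableClusteringError(
            "prediction strength is zero for every candidate threshold")
    best = int(np.argmax(means))
    cutoff = means[best] - ses[best]
    chosen = float(grid[np.nonzero(means >= cutoff)[0][0]])
    return ThresholdSearchResult(grid, means, ses, chosen, k, kernel)


# ---------------------------------------------------------------------------
# convenience front end

def spa_cluster(spectra: SpectrumSet, k: int | None = None,
                lam: float | None = None, kernel: str = "tricube",
                min_size: int | None = None, n_folds: int = 5,
                seed: int | None = 0, bandwidth: int | None = None,
                lambda_grid=None) -> tuple[ClusterSet, dict]:
    """Full SPA run: window selection, landscape, smoothing, threshold,
    cluster extraction. Returns the clusters and a provenance dict with the
    (possibly auto-selected) parameters and intermediate landscape.
    """
    if k is None:
        k = select_window_size(spectra)
    landscape = smooth_landscape(correlation_landscape(spectra, k), kernel,
                                 bandwidth)
    search = None
    if lam is None:
        search = select_threshold(spectra, lambda_grid, k, kernel, n_folds,
                                  seed, min_size, bandwidth)
        lam = search.chosen_lambda
    clusters = extract_clusters(landscape, lam, min_size)
    info = {"window_size": k, "lambda": lam, "kernel": kernel,
            "min_size": int(min_size if min_size is not None else k),
            "bandwidth": int(bandwidth if bandwidth is not None else max(2, k // 2)),
            "landscape": landscape, "threshold_search": search}
    return clusters, info
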