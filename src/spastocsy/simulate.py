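"""Simulated 1D 1H-NMR spectrum sets.

The generative model writes each observed spectrum as signal plus noise,

    y_i(f) = S_i(f) + N_i(f),           i = 1..n samples, f = 1..p points,

with the signal matrix

    S = (H Sigma + 1_n alpha^T) M,

where ``M`` (L x p) holds per-metabolite reference spectra, each row scaled
to a maximum of 1; ``alpha_l ~ chi2(gamma)`` are population mean
concentrations drawn once per dataset; ``H_il ~ N(0, phi^2)`` is the
per-sample concentration variation; and ``Sigma`` (L x L, unit-diagonal PSD)
correlates metabolites across samples. The noise ``N_i`` is a stationary
AR(1) sequence along the ppm axis with coefficient ``rho`` and stationary
standard deviation ``noise_sd`` (innovation SD = noise_sd * sqrt(1 - rho^2)).

Reference spectra for ``M`` are synthesized with realistic multiplet
structure: each metabolite resonates in 1-9 clusters, each cluster a
singlet/doublet/triplet of Lorentzian (or Gaussian) lines. The generator
records the true peak positions and support regions of every cluster so that
a matching ground-truth metabolite library can be emitted for evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectrumSet

__all__ = [
    "SimulationConfig",
    "MultipletSpec",
    "ReferenceSpectra",
    "build_reference_spectra",
    "simulate_spectra",
    "ar1_noise",
    "compute_snr",
    "simulate_snr",
]


class ResolutionError(ValueError):
    """Requested line width cannot be resolved on the ppm grid."""


def _default_sigma(L: int) -> np.ndarray:
    return np.eye(L)


@dataclass
class SimulationConfig:
    """Scenario parameters of the spectrum simulator.

    Defaults follow the simulation design used throughout the package:
    gamma = 60 degrees of freedom for chi-square concentrations, phi = 12
    concentration-units of per-sample variation, AR(1) noise with rho = 0.9,
    identity metabolite correlation, and a 0.5-4.0 ppm axis with 3500 points.
    """

    L: int = 10
    n: int = 50
    p: int = 3500
    ppm_min: float = 0.5
    ppm_max: float = 4.0
    gamma: float = 60.0
    phi: float = 12.0
    rho: float = 0.9
    sigma_matrix: np.ndarray | None = None
    noise_sd: float = 0.35
    mean_intensity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sigma_matrix is None:
            self.sigma_matrix = _default_sigma(self.L)
        self.sigma_matrix = np.asarray(self.sigma_matrix, dtype=float)
        _check_sigma(self.sigma_matrix, self.L)

    @property
    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.p)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sigma_matrix"] = np.asarray(self.sigma_matrix).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sigma_matrix") is not None:
            d["sigma_matrix"] = np.asarray(d["sigma_matrix"], dtype=float)
        return cls(**d)


def _check_sigma(sigma: np.ndarray, L: int) -> None:
    if sigma.shape != (L, L):
        raise ValueError(f"sigma_matrix must be {L}x{L}")
    if not np.allclose(sigma, sigma.T):
        raise ValueError("sigma_matrix must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0):
        raise ValueError("sigma_matrix must have unit diagonal")
    if np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise ValueError("sigma_matrix must be positive semi-definite")


@dataclass
class MultipletSpec:
    """Settings of the synthetic reference-spectrum builder.

    clusters_per_metabolite : inclusive range of resonance clusters per
        metabolite (singlet compounds up to complex multiplets).
    cluster_count_decay : geometric decay of the cluster-count law inside
        that range — small metabolites with 1-3 resonance clusters dominate
        real libraries, complex sugars with many clusters are rare.
    peaks_per_cluster : inclusive range of lines per cluster (1 = singlet,
        2 = doublet, 3 = triplet; line heights follow the binomial pattern).
    peak_spacing : range of intra-multiplet line spacings in ppm (a ~7 Hz
        J-coupling at 800 MHz is ~0.009 ppm).
    half_width : Lorentzian/Gaussian half-width at half-maximum, ppm.
    amplitude_range : per-cluster amplitudes before row rescaling, so the
        weakest cluster of a metabolite is about ``lo/hi`` of its strongest.
    signal_free_margin : ppm reserved at the low-ppm edge with no resonances,
        giving downstream noise-level estimation a clean baseline stretch.
    min_cluster_separation : minimum distance between cluster centres of one
        metabolite, ppm.
    """

    clusters_per_metabolite: tuple[int, int] = (1, 9)
    cluster_count_decay: float = 0.7
    peaks_per_cluster: tuple[int, int] = (1, 3)
    peak_spacing: tuple[float, float] = (0.006, 0.012)
    half_width: float = 0.002
    lineshape: str = "lorentzian"
    amplitude_range: tuple[float, float] = (0.2, 1.0)
    signal_free_margin: float = 0.2
    min_cluster_separation: float = 0.05
    support_threshold: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.clusters_per_metabolite
        if lo < 1 or hi < lo:
            raise ValueError("clusters_per_metabolite must be a valid range >= 1")
        lo, hi = self.peaks_per_cluster
        if lo < 1 or hi < lo:
            raise ValueError("peaks_per_cluster must be a valid range >= 1")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        if not 0 < self.amplitude_range[0] <= self.amplitude_range[1]:
            raise ValueError("amplitude_range must be positive and ordered")
        if not 0 < self.cluster_count_decay <= 1:
            raise ValueError("cluster_count_decay must be in (0, 1]")

    def noise_region(self, ppm_min: float) -> tuple[float, float]:
        """Recommended noise interval inside the signal-free margin, kept
        clear of the Lorentzian tails of the first resonances."""
        return (ppm_min, ppm_min + 0.75 * self.signal_free_margin)


@dataclass
class ReferenceSpectra:
    """Synthetic reference library spectra with ground-truth annotations.

    ``M`` is the L x p matrix of per-metabolite reference intensities (each
    row has maximum exactly 1). ``peak_table`` lists every generated line as
    (metabolite, cluster_id, peak_ppm); ``true_regions`` gives, per
    metabolite, the ppm-grid indices where the reference intensity exceeds
    ``support_threshold`` times the row maximum.
    """

    ppm_axis: np.ndarray
    M: np.ndarray
    metabolite_names: list[str]
    true_regions: list[np.ndarray]
    peak_table: pd.DataFrame = field(repr=False)
    support_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.M.shape != (len(self.metabolite_names), self.ppm_axis.size):
            raise ValueError("M shape does not match names / ppm axis")
        rowmax = self.M.max(axis=1)
        if not np.allclose(rowmax, 1.0):
            raise ValueError("every row of M must have maximum 1")
        if self.M.min() < 0 or self.M.max() > 1 + 1e-12:
            raise ValueError("M entries must lie in [0, 1]")
        for name, region in zip(self.metabolite_names, self.true_regions):
            if region.size == 0:
                raise ValueError(f"empty true region for metabolite {name}")

    @property
    def L(self) -> int:
        return self.M.shape[0]

    def subset(self, indices: np.ndarray | list[int]) -> "ReferenceSpectra":
        """Reference spectra restricted to the selected metabolites."""
        indices = np.asarray(indices, dtype=int)
        names = [self.metabolite_names[i] for i in indices]
        table = self.peak_table[self.peak_table["metabolite"].isin(names)]
        return ReferenceSpectra(self.ppm_axis, self.M[indices],
                                names, [self.true_regions[i] for i in indices],
                                table.reset_index(drop=True),
                                self.support_threshold)

    def true_signal_indices(self) -> np.ndarray:
        """Union of all metabolites' true-region grid indices."""
        if not self.true_regions:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(self.true_regions))

    def write_truth(self, path: str | Path) -> None:
        """Ground-truth sidecar: per-metabolite cluster peaks and regions."""
        out: dict = {"support_threshold": self.support_threshold, "metabolites": []}
        for i, name in enumerate(self.metabolite_names):
            rows = self.peak_table[self.peak_table["metabolite"] == name]
            clusters = [
                {"cluster_id": int(cid), "peak_ppm": sorted(float(v) for v in g["peak_ppm"])}
                for cid, g in rows.groupby("cluster_id")
            ]
            region = self.true_regions[i]
            # store contiguous index runs compactly
            runs = _index_runs(region)
            out["metabolites"].append(
                {"name": name, "clusters": clusters,
                 "true_region_runs": [[int(a), int(b)] for a, b in runs]}
            )
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


def _index_runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous inclusive (start, end) runs of a sorted index array."""
    if indices.size == 0:
        return []
    breaks = np.nonzero(np.diff(indices) > 1)[0]
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, indices.size - 1]
    return [(int(indices[a]), int(indices[b])) for a, b in zip(starts, ends)]


def _lineshape(ppm: np.ndarray, centre: float, hw: float, kind: str) -> np.ndarray:
    d = ppm - centre
    if kind == "lorentzian":
        return 1.0 / (1.0 + (d / hw) ** 2)
    # Gaussian parameterized by half-width at half-maximum
    return np.exp(-np.log(2.0) * (d / hw) ** 2)


def build_reference_spectra(
    config: SimulationConfig,
    multiplet_spec: MultipletSpec | None = None,
    rng: np.random.Generator | None = None,
) -> ReferenceSpectra:
    """Synthesize an L-row reference matrix M with multiplet structure.

    Deterministic for a fixed ``config.seed`` (or a caller-supplied ``rng``).
    Cluster centres are placed uniformly in the usable ppm range (the
    signal-free margin excluded), at least ``min_cluster_separation`` apart
    within one metabolite. Each row is rescaled to a maximum of exactly 1.
    """
    spec = multiplet_spec or MultipletSpec()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ppm = config.ppm_axis
    step = (config.ppm_max - config.ppm_min) / (config.p - 1)
    if spec.half_width < step:
        raise ResolutionError(
            f"half_width {spec.half_width} ppm is below the grid step {step:.5f} ppm; "
            "increase p or the line width"
        )
    # keep every peak (not just the cluster centre) out of the signal-free
    # margin and inside the axis: widest multiplet extent + a tail allowance
    extent = (max(spec.peaks_per_cluster) - 1) / 2.0 * max(spec.peak_spacing)
    lo_edge = config.ppm_min + spec.signal_free_margin + extent + 2 * spec.half_width
    hi_edge = config.ppm_max - extent - 2 * spec.half_width
    if hi_edge - lo_edge < spec.min_cluster_separation:
        raise ValueError("usable ppm range too narrow for the requested margins")

    rows, names, regions, records = [], [], [], []
    c_lo, c_hi = spec.clusters_per_metabolite
    k_lo, k_hi = spec.peaks_per_cluster
    counts = np.arange(c_lo, c_hi + 1)
    count_pmf = spec.cluster_count_decay ** (counts - c_lo)
    count_pmf = count_pmf / count_pmf.sum()
    for l in range(config.L):
        name = f"M{l + 1:03d}"
        n_clusters = int(rng.choice(counts, p=count_pmf))
        centres = _draw_separated(rng, lo_edge, hi_edge, n_clusters,
                                  spec.min_cluster_separation)
        row = np.zeros_like(ppm)
        for cid, centre in enumerate(sorted(centres), start=1):
            n_peaks = int(rng.integers(k_lo, k_hi + 1))
            spacing = rng.uniform(*spec.peak_spacing)
            amp = rng.uniform(*spec.amplitude_range)
            # binomial line-height pattern (1), (1,1), (1,2,1), ...
            pattern = np.array([float(math.comb(n_peaks - 1, j))
                                for j in range(n_peaks)])
            pattern /= pattern.max()
            offsets = (np.arange(n_peaks) - (n_peaks - 1) / 2.0) * spacing
            for off, height in zip(offsets, pattern):
                pos = centre + off
                row += amp * height * _lineshape(ppm, pos, spec.half_width,
                                                 spec.lineshape)
                records.append({"metabolite": name, "cluster_id": cid,
                                "peak_ppm": pos})
        row /= row.max()
        rows.append(row)
        names.append(name)
        regions.append(np.nonzero(row > spec.support_threshold)[0])

    table = pd.DataFrame.from_records(records,
                                      columns=["metabolite", "cluster_id", "peak_ppm"])
    return ReferenceSpectra(ppm, np.vstack(rows), names, regions, table,
                            spec.support_threshold)


def _draw_separated(rng: np.random.Generator, lo: float, hi: float,
                    count: int, min_sep: float, max_tries: int = 2000) -> np.ndarray:
    """Uniform draws in [lo, hi] at pairwise distance >= min_sep (rejection)."""
    centres: list[float] = []
    tries = 0
    while len(centres) < count:
        c = rng.uniform(lo, hi)
        if all(abs(c - o) >= min_sep for o in centres):
            centres.append(c)
        tries += 1
        if tries > max_tries:
            # range too crowded: relax separation rather than fail
            min_sep *= 0.5
            tries = 0
    return np.array(centres)


def ar1_noise(p: int, rho: float, noise_sd: float, rng: np.random.Generator,
              n: int = 1) -> np.ndarray:
    """Stationary AR(1) sequences along the ppm axis, shape (n, p).

    x_0 is drawn from the stationary law N(0, noise_sd^2) and the recursion
    x_t = rho x_{t-1} + e_t uses innovation SD noise_sd*sqrt(1-rho^2), so the
    marginal SD equals noise_sd at every position.
    """
    from scipy.signal import lfilter

    if noise_sd == 0:
        return np.zeros((n, p))
    innov_sd = noise_sd * np.sqrt(1.0 - rho**2)
    e = rng.normal(0.0, innov_sd, size=(n, p))
    e[:, 0] = rng.normal(0.0, noise_sd, size=n)
    return lfilter([1.0], [1.0, -rho], e, axis=1)


def simulate_spectra(
    config: SimulationConfig,
    ref: ReferenceSpectra,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumSet, SpectrumSet, pd.DataFrame]:
    """Draw one simulated dataset: (observed, signal_only, concentrations).

    ``observed = signal_only + AR(1) noise`` elementwise. Concentrations are
    the realized rows of ``H Sigma + 1 alpha^T`` (samples x metabolites) for
    ground-truth evaluation. ``alpha`` is drawn once per dataset; ``H`` is
    redrawn per sample.
    """
    if ref.ppm_axis.size != config.p:
        raise ValueError("reference ppm axis does not match config.p")
    if ref.L != config.L:
        raise ValueError("reference metabolite count does not match config.L")
    _check_sigma(np.asarray(config.sigma_matrix), config.L)
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    alpha = rng.chisquare(config.gamma, size=config.L)
    H = rng.normal(0.0, config.phi, size=(config.n, config.L))
    conc = H @ config.sigma_matrix + alpha[None, :]
    S = conc @ ref.M
    if config.mean_intensity is not None:
        scale = config.mean_intensity / S.mean()
        S = S * scale
        conc = conc * scale
    noise = ar1_noise(config.p, config.rho, config.noise_sd, rng, n=config.n)
    ids = [f"S{i + 1}" for i in range(config.n)]
    observed = SpectrumSet(ref.ppm_axis.copy(), S + noise, ids)
    signal_only = SpectrumSet(ref.ppm_axis.copy(), S, list(ids))
    conc_df = pd.DataFrame(conc, index=ids, columns=ref.metabolite_names)
    return observed, signal_only, conc_df


def identification_scenario(
    seed: int,
    library_size: int = 50,
    sample_size: int = 10,
    n: int = 50,
    gamma: float = 60.0,
    phi: float = 12.0,
    multiplet_spec: MultipletSpec | None = None,
) -> tuple[SpectrumSet, ReferenceSpectra, ReferenceSpectra, tuple[float, float]]:
    """The standard identification benchmark.

    Builds a synthetic reference library of ``library_size`` metabolites,
    draws ``sample_size`` of them into a simulated dataset of ``n`` spectra
    (chi-square concentrations with ``gamma`` degrees of freedom, per-sample
    variation ``phi``, AR(1) noise), and returns
    ``(observed, sampled_ref, library_ref, noise_region)`` — everything the
    pipeline and its scoring need.
    """
    spec = multiplet_spec or MultipletSpec()
    rng = np.random.default_rng(seed)
    lib_cfg = SimulationConfig(L=library_size, n=n, gamma=gamma, phi=phi,
                               seed=seed)
    library_ref = build_reference_spectra(lib_cfg, spec, rng)
    chosen = rng.choice(library_size, size=sample_size, replace=False)
    sampled_ref = library_ref.subset(chosen)
    sim_cfg = SimulationConfig(L=sample_size, n=n, gamma=gamma, phi=phi,
                               seed=seed)
    observed, _, _ = simulate_spectra(sim_cfg, sampled_ref, rng)
    return observed, sampled_ref, library_ref, spec.noise_region(sim_cfg.ppm_min)


def compute_snr(signal_only: SpectrumSet, observed: SpectrumSet) -> float:
    """Empirical signal-to-noise ratio of a simulated pair.

    Variance of the signal component divided by the variance of the noise
    component (observed - signal), pooled over all n x p entries.
    """
    noise = observed.intensities - signal_only.intensities
    noise_var = float(np.var(noise))
    if noise_var == 0:
        raise ValueError("noise variance is zero; SNR is undefined (infinite)")
    return float(np.var(signal_only.intensities)) / noise_var


def simulate_snr(config: SimulationConfig,
                 multiplet_spec: MultipletSpec | None = None,
                 rng: np.random.Generator | None = None) -> float:
    """SNR of one freshly simulated dataset under ``config``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ref = build_reference_spectra(config, multiplet_spec, rng)
    observed, signal_only, _ = simulate_spectra(config, ref, rng)
    return compute_snr(signal_only, observed)
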