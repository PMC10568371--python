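"""Spectrum conditioning applied before spatial clustering.

Two steps: probabilistic quotient normalization (PQN), which removes
per-sample dilution factors, and baseline zeroing, which sets datapoints
below ``baseline_k`` standard deviations of a user-chosen noise region to
zero. Baseline regions of real spectra otherwise show spuriously high
cross-sample correlations that would pollute the correlation landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectrumSet

__all__ = ["PreprocessConfig", "pqn_normalize", "baseline_zero", "preprocess"]


class AllZeroSpectrumError(ValueError):
    """A spectrum contains no positive intensity; PQN is undefined for it."""


@dataclass
class PreprocessConfig:
    """noise_region: (ppm_lo, ppm_hi) used to estimate the baseline noise SD —
    data-specific; the default suits spectra referenced to DSS/TSP with a
    signal-free stretch just above 0 ppm. For simulated spectra use the
    generator's reserved margin (``MultipletSpec.noise_region``).
    baseline_k: multiplier of that SD defining the baseline level (default 5);
    pqn_enabled: whether PQN runs before baseline zeroing."""

    noise_region: tuple[float, float] = (0.08, 0.58)
    baseline_k: float = 5.0
    pqn_enabled: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.noise_region
        if not lo < hi:
            raise ValueError("noise_region must be an ordered (lo, hi) interval")
        if self.baseline_k <= 0:
            raise ValueError("baseline_k must be > 0")


def pqn_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Probabilistic quotient normalization (Dieterle construction).

    Each spectrum is first integral-normalized, a median reference spectrum
    is computed from the normalized set, and every spectrum is divided by
    the median of its pointwise quotients against that reference (quotients
    taken where the reference is nonzero). The operation is idempotent up to
    floating tolerance.
    """
    X = spectra.intensities
    if spectra.n_samples < 2:
        raise ValueError("PQN needs at least two samples")
    totals = X.sum(axis=1)
    zero = np.nonzero(~(X > 0).any(axis=1))[0]
    if zero.size:
        bad = [spectra.sample_ids[i] for i in zero]
        raise AllZeroSpectrumError(f"all-zero spectra cannot be normalized: {bad}")
    Xi = X / totals[:, None]
    reference = np.median(Xi, axis=0)
    support = reference > 0
    if not support.any():
        raise AllZeroSpectrumError("median reference spectrum is identically zero")
    quotients = Xi[:, support] / reference[None, support]
    factors = np.median(quotients, axis=1)
    return spectra.copy_with(Xi / factors[:, None])


def baseline_zero(spectra: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Zero every datapoint below ``baseline_k`` noise-region SDs.

    The noise SD is pooled across all samples over the datapoints whose ppm
    falls in ``cfg.noise_region``. Points at or above the baseline level are
    left untouched; the operation never increases an intensity.
    """
    lo, hi = cfg.noise_region
    mask = (spectra.ppm_axis >= lo) & (spectra.ppm_axis <= hi)
    if not mask.any():
        raise ValueError(
            f"noise region {cfg.noise_region} lies outside the ppm span "
            f"({spectra.ppm_axis[0]:.3f}-{spectra.ppm_axis[-1]:.3f})"
        )
    if mask.sum() < 10:
        raise ValueError("noise region must contain at least 10 datapoints")
    sd = float(spectra.intensities[:, mask].std())
    level = cfg.baseline_k * sd
    out = spectra.intensities.copy()
    out[out < level] = 0.0
    return spectra.copy_with(out)


def preprocess(spectra: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """PQN (if enabled) followed by baseline zeroing."""
    cfg = cfg or PreprocessConfig()
    if cfg.pqn_enabled:
        try:
            spectra = pqn_normalize(spectra)
        except AllZeroSpectrumError:
            raise
    return baseline_zero(spectra, cfg)
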