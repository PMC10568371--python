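"""Scoring clusterings and identifications against simulation ground truth.

*True-signal coverage* is the percentage of ground-truth metabolite
resonance datapoints covered by the clustering; *noise coverage* is the
percentage of noise (non-resonance) datapoints covered. Under this
per-datapoint definition true coverage coincides with the true positive
rate and noise coverage with the false positive rate, which the
:class:`CoverageResult` asserts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import IdentificationReport
from .spa import ClusterSet

__all__ = ["CoverageResult", "score_coverage", "score_identification"]


@dataclass
class CoverageResult:
    true_coverage: float   # percent of true resonance datapoints covered
    noise_coverage: float  # percent of noise datapoints covered
    tpr: float
    fpr: float
    n_true_points: int
    n_noise_points: int

    def __post_init__(self) -> None:
        for v in (self.true_coverage, self.noise_coverage, self.tpr, self.fpr):
            if not 0.0 <= v <= 100.0:
                raise ValueError("rates must lie in [0, 100] percent")
        assert self.true_coverage == self.tpr
        assert self.noise_coverage == self.fpr


def score_coverage(clusters: ClusterSet, true_indices: np.ndarray,
                   n_points: int | None = None) -> CoverageResult:
    """Coverage of the ground-truth signal set by a clustering.

    ``true_indices`` is the union of all metabolites' true-region grid
    indices (e.g. ``ReferenceSpectra.true_signal_indices()``); its
    complement on the grid is the noise set.
    """
    true_indices = np.unique(np.asarray(true_indices, dtype=int))
    if true_indices.size == 0:
        raise ValueError("empty ground truth")
    p = int(n_points if n_points is not None else clusters.ppm_axis.size)
    truth = np.zeros(p, dtype=bool)
    truth[true_indices] = True
    covered = np.zeros(p, dtype=bool)
    idx = clusters.covered_indices()
    covered[idx] = True
    n_true = int(truth.sum())
    n_noise = p - n_true
    tc = 100.0 * np.count_nonzero(covered & truth) / n_true
    nc = 100.0 * np.count_nonzero(covered & ~truth) / n_noise if n_noise else 0.0
    return CoverageResult(tc, nc, tc, nc, n_true, n_noise)


def score_identification(report: IdentificationReport, truth_names
                         ) -> tuple[int, int, int]:
    """(n_correct, n_missed, n_false) of identified vs truly present names."""
    truth = set(truth_names)
    if not truth:
        raise ValueError("truth_names must be nonempty")
    identified = set(report.identified_names)
    return (len(identified & truth), len(truth - identified),
            len(identified - truth))
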