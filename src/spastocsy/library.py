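"""Reference-library matching of STOCSY groups.

A metabolite library lists, per metabolite, its resonance clusters and
their peak chemical shifts. A library cluster counts as *detected* by a
STOCSY group when at least one of its reference peaks lies within a ppm
tolerance (default +/-0.025 ppm) of a peak detected in that group. Each
metabolite's *detection ratio* is the best fraction, over groups, of its
library clusters (inside the scoring window, default 0.5-4.0 ppm) detected
by a single group; a metabolite is *identified* when the ratio strictly
exceeds the detection threshold (default 0.55 — e.g. a nine-cluster
metabolite needs at least five detected clusters). A *singlet filter*
optionally admits single-cluster metabolites only when the matching group
is itself a singleton (self-correlated only), suppressing accidental
matches inside multi-cluster groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dataset import SpectrumSet
from .spa import ClusterSet
from .stocsy import StocsyGroupSet

__all__ = [
    "MetaboliteLibrary",
    "IdentificationReport",
    "detect_cluster_peaks",
    "match_metabolites",
]

DEFAULT_TOLERANCE = 0.025
DEFAULT_DETECTION_THRESHOLD = 0.55
DEFAULT_PPM_WINDOW = (0.5, 4.0)


class LibraryFormatError(ValueError):
    """Malformed metabolite library file."""


@dataclass
class MetaboliteLibrary:
    """Reference resonance clusters: one row per peak.

    ``table`` columns: metabolite, cluster_id, peak_ppm. ``ppm_window``
    bounds the scoring range; a cluster is *in window* when at least one of
    its peaks falls inside.
    """

    table: pd.DataFrame
    ppm_window: tuple[float, float] = DEFAULT_PPM_WINDOW

    def __post_init__(self) -> None:
        required = {"metabolite", "cluster_id", "peak_ppm"}
        if not required.issubset(self.table.columns):
            raise LibraryFormatError(
                f"library table must have columns {sorted(required)}")
        lo, hi = self.ppm_window
        in_win = self.table["peak_ppm"].between(lo, hi)
        counts = self.table[in_win].groupby("metabolite")["cluster_id"].nunique()
        missing = set(self.table["metabolite"]) - set(counts.index)
        if missing:
            raise LibraryFormatError(
                f"metabolites with no cluster inside the ppm window: {sorted(missing)}")

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.table["metabolite"].unique())

    def clusters_in_window(self, metabolite: str) -> dict[int, np.ndarray]:
        """cluster_id -> in-window peak ppms, for clusters with >= 1 such peak."""
        lo, hi = self.ppm_window
        rows = self.table[(self.table["metabolite"] == metabolite)
                          & self.table["peak_ppm"].between(lo, hi)]
        return {int(cid): g["peak_ppm"].to_numpy()
                for cid, g in rows.groupby("cluster_id")}

    @classmethod
    def from_csv(cls, path: str | Path,
                 ppm_window: tuple[float, float] = DEFAULT_PPM_WINDOW
                 ) -> "MetaboliteLibrary":
        df = pd.read_csv(path)
        if not {"metabolite", "cluster_id", "peak_ppm"}.issubset(df.columns):
            raise LibraryFormatError(
                f"{path}: expected header metabolite,cluster_id,peak_ppm")
        bad = df.index[pd.to_numeric(df["peak_ppm"], errors="coerce").isna()]
        if len(bad):
            raise LibraryFormatError(
                f"{path}: non-numeric peak_ppm at data line(s) {[i + 2 for i in bad]}")
        df["peak_ppm"] = df["peak_ppm"].astype(float)
        return cls(df, ppm_window)

    @classmethod
    def from_reference_spectra(cls, ref,
                               ppm_window: tuple[float, float] | None = None
                               ) -> "MetaboliteLibrary":
        """Ground-truth library emitted by the simulator's reference builder."""
        window = ppm_window or (float(ref.ppm_axis[0]), float(ref.ppm_axis[-1]))
        return cls(ref.peak_table.copy(), window)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class IdentificationReport:
    """Per-metabolite detection ratios plus unannotated candidate groups.

    ``table`` columns: metabolite, n_library_clusters, n_detected_clusters,
    detection_ratio, identified, matched_group_id, singlet_filtered.
    ``unannotated`` lists groups whose peaks matched no library cluster:
    (group_id, member cluster ids, detected peak ppms).
    """

    table: pd.DataFrame
    unannotated: list[dict] = field(default_factory=list)

    @property
    def identified_names(self) -> list[str]:
        if self.table.empty:
            return []
        return sorted(self.table.loc[self.table["identified"], "metabolite"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def detect_cluster_peaks(spectra: SpectrumSet, clusters: ClusterSet
                         ) -> list[np.ndarray]:
    """Peak ppm positions per cluster, picked on the mean spectrum.

    Strict local-maximum comparison (plateau apexes take the midpoint);
    a cluster without interior maxima reports its maximum position.
    """
    mean = spectra.mean_spectrum()
    out = []
    for c in clusters:
        seg = mean[c.start_index:c.end_index + 1]
        peaks, _ = find_peaks(seg)
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(seg))])
        out.append(spectra.ppm_axis[c.start_index + peaks])
    return out


def match_metabolites(groups: StocsyGroupSet, clusters: ClusterSet,
                      peaks: list[np.ndarray], library: MetaboliteLibrary,
                      tolerance: float = DEFAULT_TOLERANCE,
                      detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
                      singlet_filter: bool = True) -> IdentificationReport:
    """Score every library metabolite against the STOCSY groups.

    ``peaks`` is the per-cluster peak list from :func:`detect_cluster_peaks`,
    indexed like ``clusters``. Matching is non-exclusive: one detected peak
    may support several metabolites, and one library cluster is detected as
    soon as any of its reference peaks is within ``tolerance`` of any peak
    of the group under consideration.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not 0 < detection_threshold < 1:
        raise ValueError("detection_threshold must be in (0, 1)")
    if len(peaks) != len(clusters):
        raise ValueError("peaks list must align with the cluster set")

    group_peaks: dict[int, np.ndarray] = {}
    for g, members in groups.groups.items():
        vals = [peaks[cid] for cid in members if peaks[cid].size]
        group_peaks[g] = np.sort(np.concatenate(vals)) if vals else np.empty(0)

    def group_detects(ref_peaks: np.ndarray, gp: np.ndarray) -> bool:
        if gp.size == 0:
            return False
        pos = np.searchsorted(gp, ref_peaks)
        left = gp[np.clip(pos - 1, 0, gp.size - 1)]
        right = gp[np.clip(pos, 0, gp.size - 1)]
        return bool(np.any(np.minimum(np.abs(ref_peaks - left),
                                      np.abs(ref_peaks - right)) <= tolerance))

    rows = []
    matched_groups: set[int] = set()
    for met in library.metabolites:
        lib_clusters = library.clusters_in_window(met)
        total = len(lib_clusters)
        best_ratio, best_detected, best_group = 0.0, 0, None
        best_groups: list[int] = []
        for g, gp in group_peaks.items():
            detected = sum(group_detects(ref_peaks, gp)
                           for ref_peaks in lib_clusters.values())
            ratio = detected / total
            if ratio > best_ratio:
                best_ratio, best_detected, best_group = ratio, detected, g
                best_groups = [g]
            elif ratio == best_ratio and ratio > 0:
                best_groups.append(g)
        identified = best_ratio > detection_threshold
        filtered = False
        if identified and singlet_filter and total == 1:
            # a single-cluster metabolite is kept only when it can be
            # attributed to a self-correlated (singleton) group; among
            # equally matching groups the self-correlated one wins
            self_corr = [g for g in best_groups
                         if groups.singleton_flags.get(g, False)]
            if self_corr:
                best_group = self_corr[0]
            else:
                identified = False
                filtered = True
        if best_detected > 0 and best_group is not None:
            matched_groups.add(best_group)
        rows.append({"metabolite": met, "n_library_clusters": total,
                     "n_detected_clusters": best_detected,
                     "detection_ratio": best_ratio, "identified": identified,
                     "matched_group_id": best_group,
                     "singlet_filtered": filtered})

    # groups whose peaks matched no library cluster at all: candidates for
    # metabolites absent from the library
    all_ref = {met: library.clusters_in_window(met) for met in library.metabolites}
    unannotated = []
    for g, gp in group_peaks.items():
        hit = any(group_detects(rp, gp)
                  for met_clusters in all_ref.values()
                  for rp in met_clusters.values())
        if not hit:
            unannotated.append({"group_id": g,
                                "cluster_ids": list(groups.groups[g]),
                                "peak_ppm": [float(v) for v in gp]})

    columns = ["metabolite", "n_library_clusters", "n_detected_clusters",
               "detection_ratio", "identified", "matched_group_id",
               "singlet_filtered"]
    table = pd.DataFrame(rows, columns=columns)
    return IdentificationReport(table, unannotated)
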