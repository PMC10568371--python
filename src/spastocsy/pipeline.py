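"""End-to-end SPA-STOCSY pipeline: preprocess -> SPA -> STOCSY -> identify.

Every stage output (landscape, clusters, groups, report) can be written to
an output directory together with a provenance record (parameters actually
used, including auto-selected ones, plus seed and package version), so a
fixed configuration reproduces bit-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import SpectrumSet, read_spectra
from .library import (MetaboliteLibrary, IdentificationReport,
                      detect_cluster_peaks, match_metabolites)
from .preprocess import PreprocessConfig, baseline_zero, pqn_normalize
from .spa import ClusterSet, spa_cluster
from .stocsy import (ClusterIntensityMatrix, StocsyGroupSet,
                     calibrate_threshold, cluster_intensities, group_clusters,
                     stocsy_correlate)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("spastocsy")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full SPA-STOCSY run.

    ``window_size``/``spa_lambda``/``stocsy_threshold`` set to None mean
    "select automatically from the data" (PACF, prediction strength, and
    internal-standard calibration respectively; calibration requires
    ``reference_cluster_ids``, otherwise 0.8 is used).
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window_size: int | None = None
    spa_lambda: float | None = None
    kernel: str = "tricube"
    bandwidth: int | None = None
    min_size: int | None = None
    n_folds: int = 5
    lambda_grid: list[float] | None = None
    stocsy_threshold: float | None = 0.8
    reference_cluster_ids: list[int] | None = None
    tolerance: float = 0.025
    detection_threshold: float = 0.55
    singlet_filter: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    preprocessed: SpectrumSet
    clusters: ClusterSet
    intensities: ClusterIntensityMatrix
    groups: StocsyGroupSet
    peaks: list[np.ndarray]
    report: IdentificationReport
    provenance: dict


def run_pipeline(spectra: SpectrumSet | str | Path,
                 library: MetaboliteLibrary | str | Path,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run preprocess -> SPA -> STOCSY -> library matching.

    ``spectra`` and ``library`` may be objects or paths to their delimited
    text representations. With ``outdir`` set, all intermediates and a
    provenance JSON are written there.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    if not isinstance(spectra, SpectrumSet):
        spectra = read_spectra(spectra)
    if not isinstance(library, MetaboliteLibrary):
        library = MetaboliteLibrary.from_csv(library)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    prov: dict = {"version": __version__, "seed": config.seed,
                  "n_samples": spectra.n_samples, "n_points": spectra.n_points}

    stage = "preprocess"
    try:
        pp = spectra
        if config.preprocess.pqn_enabled:
            pp = pqn_normalize(pp)
        pp = baseline_zero(pp, config.preprocess)
        prov["preprocess"] = {"pqn": config.preprocess.pqn_enabled,
                              "noise_region": list(config.preprocess.noise_region),
                              "baseline_k": config.preprocess.baseline_k}

        stage = "spa"
        clusters, info = spa_cluster(
            pp, k=config.window_size, lam=config.spa_lambda,
            kernel=config.kernel, min_size=config.min_size,
            n_folds=config.n_folds, seed=config.seed,
            bandwidth=config.bandwidth, lambda_grid=config.lambda_grid)
        prov["spa"] = {"window_size": info["window_size"],
                       "lambda": info["lambda"], "kernel": info["kernel"],
                       "min_size": info["min_size"],
                       "n_clusters": len(clusters)}
        log.info("SPA: k=%d lambda=%.3f -> %d clusters",
                 info["window_size"], info["lambda"], len(clusters))
        if out is not None:
            _write_clusters(clusters, out / "clusters.csv")
            np.savetxt(out / "landscape.csv",
                       np.column_stack([pp.ppm_axis, info["landscape"].values]),
                       delimiter=",", header="ppm,landscape", comments="")

        stage = "stocsy"
        intens = cluster_intensities(pp, clusters)
        corr = stocsy_correlate(intens)
        threshold = config.stocsy_threshold
        if threshold is None:
            if not config.reference_cluster_ids:
                threshold = 0.8
            else:
                threshold = calibrate_threshold(intens,
                                                config.reference_cluster_ids)
        groups = group_clusters(corr, threshold, intens.cluster_ids)
        prov["stocsy"] = {"threshold": threshold, "n_groups": len(groups.groups)}
        log.info("STOCSY: threshold=%.2f -> %d groups", threshold,
                 len(groups.groups))
        if out is not None:
            pd.DataFrame(corr).to_csv(out / "correlation.csv", index=False)
            rows = [(cid, g) for g, members in groups.groups.items()
                    for cid in members]
            pd.DataFrame(rows, columns=["cluster_id", "group_id"]) \
                .to_csv(out / "groups.csv", index=False)

        stage = "identify"
        peaks = detect_cluster_peaks(pp, clusters)
        report = match_metabolites(groups, clusters, peaks, library,
                                   config.tolerance,
                                   config.detection_threshold,
                                   config.singlet_filter)
        prov["identify"] = {"tolerance": config.tolerance,
                            "detection_threshold": config.detection_threshold,
                            "singlet_filter": config.singlet_filter,
                            "n_identified": len(report.identified_names)}
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        if out is not None:
            (out / "provenance.json").write_text(json.dumps(prov, indent=1))
        raise PipelineStageError(stage, exc) from exc

    prov["runtime_s"] = round(time.time() - t0, 3)
    if out is not None:
        report.to_csv(out / "report.csv")
        (out / "unannotated.json").write_text(json.dumps(report.unannotated,
                                                         indent=1))
        (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    log.info("pipeline finished in %.2fs; %d metabolites identified",
             prov["runtime_s"], prov["identify"]["n_identified"])
    return PipelineResult(pp, clusters, intens, groups, peaks, report, prov)


def _write_clusters(clusters: ClusterSet, path: Path) -> None:
    rows = [(i, c.start_ppm, c.end_ppm, c.start_index, c.end_index,
             c.member_count) for i, c in enumerate(clusters)]
    pd.DataFrame(rows, columns=["cluster_id", "start_ppm", "end_ppm",
                                "start_idx", "end_idx", "n_points"]) \
        .to_csv(path, index=False)
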