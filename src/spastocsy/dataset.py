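"""Core spectrum container and delimited-text I/O.

A :class:`SpectrumSet` is the universal exchange object of the package: a
strictly monotone chemical-shift (ppm) axis plus an ``n_samples x n_points``
intensity matrix. Spectra are stored as comma-delimited text whose first row
is ``ppm,<axis values...>`` and whose subsequent rows are
``<sample_id>,<intensities...>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "read_spectra", "write_spectra"]


@dataclass
class SpectrumSet:
    """Aligned 1D NMR spectra on a shared ppm grid.

    Parameters
    ----------
    ppm_axis : ndarray, shape (p,)
        Chemical shifts, strictly monotone increasing.
    intensities : ndarray, shape (n, p)
        One row per sample, finite values.
    sample_ids : list of str
        Unique sample labels; generated as ``S1..Sn`` when omitted.
    """

    ppm_axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm_axis.ndim != 1:
            raise ValueError("ppm_axis must be one-dimensional")
        if self.intensities.shape[1] != self.ppm_axis.size:
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} columns "
                f"but ppm axis has {self.ppm_axis.size} points"
            )
        diffs = np.diff(self.ppm_axis)
        if self.ppm_axis.size >= 2 and np.all(diffs < 0):
            # descending axis: store ascending, reorder columns consistently
            self.ppm_axis = self.ppm_axis[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()
        elif self.ppm_axis.size >= 2 and not np.all(diffs > 0):
            raise ValueError("ppm_axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length does not match number of spectra")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def mean_spectrum(self) -> np.ndarray:
        """Mean intensity across samples at each ppm position."""
        return self.intensities.mean(axis=0)

    def copy_with(self, intensities: np.ndarray) -> "SpectrumSet":
        """New SpectrumSet sharing this axis and sample ids."""
        return SpectrumSet(self.ppm_axis.copy(), np.asarray(intensities, float),
                           list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.sample_ids,
                            columns=self.ppm_axis)


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet as delimited text (first row = ppm axis)."""
    with open(path, "w") as fh:
        fh.write("ppm," + ",".join(repr(float(v)) for v in spectra.ppm_axis) + "\n")
        for sid, row in zip(spectra.sample_ids, spectra.intensities):
            fh.write(str(sid) + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a SpectrumSet from delimited text.

    The first row must start with ``ppm`` followed by the axis values; each
    subsequent row is a sample id followed by one intensity per axis point.
    Descending axes are accepted and reversed. Ragged rows, non-numeric cells
    and duplicate sample ids are rejected with row diagnostics.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    fields = header.split(",")
    if not fields or fields[0].strip().lower() != "ppm":
        raise ValueError(f"{path}: first row must begin with 'ppm'")
    try:
        ppm = np.array([float(v) for v in fields[1:]], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric ppm value in header ({exc})") from exc
    df = pd.read_csv(path, skiprows=1, header=None, index_col=0,
                     float_precision="round_trip")
    if df.shape[1] != ppm.size:
        bad = [str(i) for i, row in enumerate(df.itertuples(index=False), start=2)
               if sum(pd.notna(v) for v in row) != ppm.size]
        raise ValueError(
            f"{path}: rows have {df.shape[1]} values but ppm axis has {ppm.size} "
            f"(check rows {', '.join(bad) or 'all'})"
        )
    coerced = df.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().to_numpy().any():
        bad_rows = list(coerced.index[coerced.isna().any(axis=1)])
        raise ValueError(f"{path}: non-numeric or missing cells in rows {bad_rows}")
    return SpectrumSet(ppm, coerced.to_numpy(dtype=float), [str(i) for i in df.index])
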