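"""Spectral data container and CSV I/O.

The on-disk dialect is a wide CSV: header row ``sample_id,<wavelength>,...``
with one row per fruit.  Dark-current and white-reference spectra use the
same header with a single row (``sample_id`` = ``dark`` / ``white``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "read_spectra", "write_spectra", "read_reference", "write_reference"]


class SpectralFormatError(ValueError):
    """Raised when spectra violate the wide-CSV contract (grid, IDs, finiteness)."""


@dataclass
class SpectrumSet:
    """Samples-by-wavelengths intensity matrix on a shared ascending grid.

    Parameters
    ----------
    wavelengths : (p,) float array, strictly ascending, nanometres.
    intensities : (n, p) float array.
    sample_ids : length-n sequence of unique strings.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.wavelengths.ndim != 1:
            raise SpectralFormatError("wavelength grid must be one-dimensional")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectralFormatError("wavelength grid must be strictly ascending")
        if self.intensities.shape[0] == 0:
            self.intensities = self.intensities.reshape(0, self.wavelengths.size)
        if self.intensities.shape[1] != self.wavelengths.size:
            raise SpectralFormatError(
                f"intensity matrix has {self.intensities.shape[1]} columns, "
                f"grid has {self.wavelengths.size} wavelengths"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise SpectralFormatError("one sample_id required per spectrum")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectralFormatError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """Same grid and IDs, new matrix (the shape all transforms preserve)."""
        return SpectrumSet(self.wavelengths, intensities, list(self.sample_ids))

    def select(self, indices: np.ndarray) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(self.wavelengths[idx], self.intensities[:, idx], list(self.sample_ids))

    def subset(self, ids: list[str]) -> "SpectrumSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in ids]
        return SpectrumSet(self.wavelengths, self.intensities[rows], list(ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def write_spectra(spectra: SpectrumSet, path) -> None:
    spectra.to_frame().to_csv(path, index=False)


def read_spectra(path) -> SpectrumSet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SpectralFormatError(f"{path}: missing sample_id column")
    wl = np.array([float(c) for c in df.columns[1:]])
    return SpectrumSet(wl, df.iloc[:, 1:].to_numpy(float), df["sample_id"].tolist())


def write_reference(wavelengths: np.ndarray, values: np.ndarray, name: str, path) -> None:
    write_spectra(SpectrumSet(wavelengths, values[None, :], [name]), path)


def read_reference(path) -> tuple[np.ndarray, np.ndarray]:
    ss = read_spectra(path)
    if ss.n_samples != 1:
        raise SpectralFormatError(f"{path}: reference file must contain exactly one spectrum")
    return ss.wavelengths, ss.intensities[0]
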