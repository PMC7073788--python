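"""Spectral dataset container and delimited-text I/O.

The on-disk layout is a plain CSV whose header row carries the wavelength
axis in nm: ``sample_id,cultivar,<wl_1>,<wl_2>,...``; each following row is
one averaged sample spectrum.  A sidecar JSON manifest records the
simulation configuration and ground truth when the file was simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "read_dataset", "write_dataset"]


@dataclass
class SpectralDataset:
    """Matrix of emission spectra with a shared wavelength axis.

    Attributes
    ----------
    wavelengths : ndarray, shape (n_variables,)
        Strictly increasing wavelength axis in nm.
    intensities : ndarray, shape (n_samples, n_variables)
        One spectrum per row, arbitrary intensity units.
    labels : ndarray of int, shape (n_samples,)
        Cultivar codes 1, 2, 3 (per-cultivar acquisition order is the row
        order within each label block).
    sample_ids : list of str
        Stable identifiers, e.g. ``"C1-07"``.
    meta : dict
        Free-form provenance (simulation config echo, preprocessing trail).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if self.wavelengths.shape != (p,):
            raise ValueError(
                f"axis length {self.wavelengths.size} != {p} intensity columns"
            )
        if self.labels.shape != (n,):
            raise ValueError("one label per sample required")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    def replace(self, **kw) -> "SpectralDataset":
        """Shallow copy with selected fields overridden."""
        data = {
            "wavelengths": self.wavelengths,
            "intensities": self.intensities,
            "labels": self.labels,
            "sample_ids": list(self.sample_ids),
            "meta": dict(self.meta),
        }
        data.update(kw)
        return SpectralDataset(**data)


def write_dataset(dataset: SpectralDataset, path: str | Path,
                  manifest: dict | None = None) -> None:
    """Write the CSV layout described in the module docstring.

    If `manifest` is given (or the dataset carries meta), a ``<path>.json``
    manifest is written alongside.
    """
    path = Path(path)
    cols = ["sample_id", "cultivar"] + [f"{w:.6f}" for w in dataset.wavelengths]
    frame = pd.DataFrame(
        np.round(dataset.intensities, 6), columns=cols[2:], copy=False
    )
    frame.insert(0, "cultivar", dataset.labels)
    frame.insert(0, "sample_id", dataset.sample_ids)
    frame.to_csv(path, index=False, float_format="%.6g")
    manifest = manifest if manifest is not None else dataset.meta
    if manifest:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )


def read_dataset(path: str | Path) -> SpectralDataset:
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: expected sample_id, cultivar and spectra columns")
    wavelengths = np.array([float(c) for c in frame.columns[2:]])
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SpectralDataset(
        wavelengths=wavelengths,
        intensities=frame.iloc[:, 2:].to_numpy(dtype=float),
        labels=frame["cultivar"].to_numpy(dtype=int),
        sample_ids=[str(s) for s in frame["sample_id"]],
        meta=meta,
    )
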