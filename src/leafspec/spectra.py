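"""Leaf reflectance spectra: reading, replicate averaging and regridding.

Spectra arrive as wide CSV (EcoSIS-style): ``leaf_id, replicate`` followed by
one column per nanometre over the 350-2500 nm detector range.  Replicate
scans of one leaf are averaged, and spectra are linearly interpolated onto a
common 1 nm grid (default 500-2400 nm, trimming noisy detector edges) to form
the predictor matrix used by the PLSR models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraMatrix",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "regrid",
    "build_matrix",
]

#: reflectance slightly above 1 happens with imperfect white references
_MAX_REFLECTANCE = 1.2


@dataclass
class Spectrum:
    """Reflectance of one leaf scan on a strictly increasing wavelength axis."""

    leaf_id: str
    wavelengths: np.ndarray  # nm
    reflectance: np.ndarray  # fraction, [0, 1.2]
    replicate_index: int | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.wavelengths < 350) or np.any(self.wavelengths > 2500):
            raise ValueError("wavelengths outside the 350-2500 nm instrument range")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance values")
        if np.any(self.reflectance > _MAX_REFLECTANCE) or np.any(self.reflectance < 0):
            warnings.warn(
                f"leaf {self.leaf_id!r}: reflectance outside [0, {_MAX_REFLECTANCE}]; "
                "values will be clipped on regridding",
                RuntimeWarning,
            )


@dataclass
class SpectraMatrix:
    """One averaged spectrum per leaf on a shared wavelength grid."""

    leaf_ids: np.ndarray
    wavelengths: np.ndarray
    values: np.ndarray  # (n_leaves, n_wavelengths)

    def __post_init__(self) -> None:
        self.leaf_ids = np.asarray(self.leaf_ids)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.leaf_ids.size, self.wavelengths.size):
            raise ValueError("values shape must be (n_leaves, n_wavelengths)")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "leaf_id", self.leaf_ids)
        return df

    def subset(self, leaf_ids) -> "SpectraMatrix":
        idx = pd.Index(self.leaf_ids).get_indexer(leaf_ids)
        if np.any(idx < 0):
            raise KeyError("unknown leaf_id in subset request")
        return SpectraMatrix(np.asarray(leaf_ids), self.wavelengths, self.values[idx])


def read_spectra(path) -> list[Spectrum]:
    """Parse a wide spectra CSV into individual replicate spectra.

    Expected layout: columns ``leaf_id``, ``replicate`` (optional), then one
    numeric column per wavelength in nm, in increasing order.
    """
    df = pd.read_csv(path)
    if "leaf_id" not in df.columns:
        raise ValueError("spectra CSV must have a leaf_id column")
    meta_cols = [c for c in ("leaf_id", "replicate") if c in df.columns]
    wl_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column header: {exc}") from None
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength columns must be sorted increasing")
    values = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-numeric or missing reflectance values")
    spectra = []
    for i, (_, row) in enumerate(df.iterrows()):
        rep = int(row["replicate"]) if "replicate" in meta_cols else None
        spectra.append(
            Spectrum(
                leaf_id=str(row["leaf_id"]),
                wavelengths=wavelengths,
                reflectance=values[i],
                replicate_index=rep,
            )
        )
    return spectra


def write_spectra(spectra: list[Spectrum], path) -> None:
    """Write replicate spectra back to the wide CSV layout (round-trips read_spectra)."""
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths
    rows = []
    for s in spectra:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid to be written")
        row = {"leaf_id": s.leaf_id}
        if s.replicate_index is not None:
            row["replicate"] = s.replicate_index
        row.update({f"{w:g}": v for w, v in zip(wl, s.reflectance)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Per-wavelength arithmetic mean of replicate scans of one leaf."""
    if not 1 <= len(spectra) <= 8:
        raise ValueError(f"expected 1-8 replicates, got {len(spectra)}")
    leaf_ids = {s.leaf_id for s in spectra}
    if len(leaf_ids) != 1:
        raise ValueError(f"replicates from multiple leaves: {sorted(leaf_ids)}")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("replicates on mismatched wavelength grids")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return Spectrum(leaf_id=spectra[0].leaf_id, wavelengths=wl, reflectance=mean)


def regrid(
    spectrum: Spectrum,
    grid_start: float = 500.0,
    grid_end: float = 2400.0,
    step: float = 1.0,
) -> np.ndarray:
    """Linearly interpolate a spectrum onto the integer-nm analysis grid.

    Values are clipped to [0, 1.2].  The requested window must lie inside
    the measured range.
    """
    wl = spectrum.wavelengths
    if grid_start < wl[0] or grid_end > wl[-1]:
        raise ValueError(
            f"requested grid {grid_start}-{grid_end} nm outside measured "
            f"range {wl[0]:g}-{wl[-1]:g} nm"
        )
    grid = grid_wavelengths(grid_start, grid_end, step)
    out = np.interp(grid, wl, spectrum.reflectance)
    return np.clip(out, 0.0, _MAX_REFLECTANCE)


def grid_wavelengths(grid_start: float = 500.0, grid_end: float = 2400.0, step: float = 1.0):
    """The analysis wavelength grid (inclusive of both ends)."""
    n = int(round((grid_end - grid_start) / step)) + 1
    return grid_start + step * np.arange(n)


def build_matrix(
    spectra: list[Spectrum],
    grid_start: float = 500.0,
    grid_end: float = 2400.0,
    step: float = 1.0,
) -> SpectraMatrix:
    """Average replicates per leaf and regrid into the PLSR predictor matrix.

    Leaves appear in order of first occurrence.
    """
    by_leaf: dict[str, list[Spectrum]] = {}
    for s in spectra:
        by_leaf.setdefault(s.leaf_id, []).append(s)
    grid = grid_wavelengths(grid_start, grid_end, step)
    rows = [
        regrid(average_replicates(reps), grid_start, grid_end, step)
        for reps in by_leaf.values()
    ]
    return SpectraMatrix(
        leaf_ids=np.array(list(by_leaf)), wavelengths=grid, values=np.array(rows)
    )
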