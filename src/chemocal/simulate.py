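"""Synthetic UV mixture spectra under the bilinear Beer-Lambert model.

Measured pure-component spectra for this six-component system are not
publicly tabulated, so this module provides a synthetic stand-in: Gaussian
band shapes on the fixed 230.0-266.0 nm grid (0.1 nm, 361 points), mixed
bilinearly as ``A = C @ S.T + E`` with additive homoscedastic Gaussian
noise.  Concentrations are in ug/mL with a 1 cm path length implicit, so
each pure "sensitivity" spectrum carries units of absorbance per (ug/mL).

The default six-band library is deliberately heavily overlapping (pairwise
Pearson correlation of any two pure spectra >= 0.5) to emulate the strongly
interfering drug/impurity spectra the multivariate models are meant to
resolve.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ANALYTES, ConcentrationDesign

__all__ = [
    "GRID_START_NM",
    "GRID_STEP_NM",
    "N_POINTS",
    "wavelength_grid",
    "PureSpectrum",
    "SpectraMatrix",
    "gaussian_pure_spectrum",
    "default_library",
    "simulate_dataset",
    "write_spectra_csv",
    "read_spectra_csv",
]

GRID_START_NM = 230.0
GRID_STEP_NM = 0.1
N_POINTS = 361


def wavelength_grid() -> np.ndarray:
    """The 361-point grid 230.0, 230.1, ..., 266.0 nm, computed by index."""
    return GRID_START_NM + GRID_STEP_NM * np.arange(N_POINTS)


@dataclasses.dataclass(frozen=True)
class PureSpectrum:
    """Sensitivity spectrum of one analyte: absorbance per (ug/mL), 1 cm path."""

    analyte: str
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivity, dtype=float)
        if s.shape != (N_POINTS,):
            raise ValueError(f"sensitivity must have {N_POINTS} points, got {s.shape}")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("sensitivity must be finite and non-negative")
        object.__setattr__(self, "sensitivity", s)


@dataclasses.dataclass(frozen=True)
class SpectraMatrix:
    """Absorbance matrix, samples x 361, with sample identifiers."""

    absorbance: np.ndarray
    sample_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2 or a.shape[1] != N_POINTS:
            raise ValueError(f"absorbance must be n x {N_POINTS}, got {a.shape}")
        if a.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match row count")
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "sample_ids", tuple(int(i) for i in self.sample_ids))

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def rows(self, ids) -> np.ndarray:
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        return self.absorbance[[pos[int(i)] for i in sorted(ids)]]


def gaussian_pure_spectrum(
    analyte: str, bands: Sequence[tuple[float, float, float]]
) -> PureSpectrum:
    """Sum-of-Gaussians pure spectrum from (center nm, width nm, height) bands.

    ``sensitivity(lam) = sum_b height_b * exp(-(lam - center_b)^2 / (2 width_b^2))``
    evaluated on the fixed grid.  Heights are absorbance * mL / ug.
    """
    if len(bands) == 0:
        raise ValueError("band list must not be empty")
    lam = wavelength_grid()
    s = np.zeros(N_POINTS)
    for center, width, height in bands:
        if not (200.0 <= center <= 400.0):
            raise ValueError(f"band center {center} nm outside [200, 400]")
        if width <= 0:
            raise ValueError("band width must be > 0")
        if height < 0:
            raise ValueError("band height must be >= 0")
        s += height * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
    return PureSpectrum(analyte=analyte, sensitivity=s)


#: Band presets (center nm, Gaussian sigma nm, height) per analyte.  Every
#: analyte has a strong band in the shared 243-246 nm absorption region
#: (sigma ~4 nm, i.e. ~9 nm FWHM), which makes all pure spectra heavily
#: overlapping (pairwise congruence >= 0.69), plus a narrower secondary
#: band near one edge of the window that carries its distinguishing
#: structure, the way real drug/impurity spectra differ through shoulders
#: and secondary maxima.  Heights are balanced so each analyte contributes
#: comparable absorbance at its design concentrations, and so the strongest
#: design mixture stays almost exactly 2 absorbance units.
DEFAULT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "PAR": ((244.8, 3.9, 0.0771), (255.5, 1.25, 0.1032)),
    "HYO": ((243.6, 3.9, 0.0176), (266.0, 1.25, 0.0206)),
    "PNP": ((244.1, 3.9, 0.0605), (259.0, 1.25, 0.0639)),
    "PCA": ((244.8, 3.9, 0.2572), (229.5, 1.25, 0.2577)),
    "TRO": ((245.3, 4.0, 0.0240), (233.3, 1.25, 0.0265)),
    "PAP": ((243.9, 4.0, 0.0637), (262.5, 1.25, 0.0638)),
}


def default_library() -> tuple[PureSpectrum, ...]:
    """The six default pure spectra, in the analyte column order."""
    return tuple(
        gaussian_pure_spectrum(name, DEFAULT_BANDS[name]) for name in ANALYTES
    )


def library_matrix(library: Sequence[PureSpectrum]) -> np.ndarray:
    """Stack a library into the 361 x k sensitivity matrix S."""
    return np.column_stack([p.sensitivity for p in library])


def simulate_dataset(
    design: ConcentrationDesign,
    library: Sequence[PureSpectrum] | None = None,
    noise_sd: float = 0.002,
    seed: int | None = None,
) -> SpectraMatrix:
    """Simulate mixture spectra ``A = C @ S.T + E`` for a concentration design.

    ``E`` is iid Normal(0, noise_sd^2); the draw is deterministic given
    ``seed``.  The library order must match the design's analyte order.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if library is None:
        library = default_library()
    if tuple(p.analyte for p in library) != tuple(design.analytes):
        raise ValueError(
            f"library order {[p.analyte for p in library]} does not match "
            f"design analytes {list(design.analytes)}"
        )
    S = library_matrix(library)
    A = design.concentrations @ S.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return SpectraMatrix(absorbance=A, sample_ids=tuple(range(1, design.n_runs + 1)))


# ---------------------------------------------------------------------------
# CSV interface: first column wavelength_nm (1 dp), one column per sample id.

def write_spectra_csv(spectra: SpectraMatrix, path) -> None:
    df = pd.DataFrame(
        spectra.absorbance.T,
        columns=[str(i) for i in spectra.sample_ids],
    )
    df.insert(0, "wavelength_nm", [f"{w:.1f}" for w in wavelength_grid()])
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraMatrix:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra CSV must have a wavelength_nm column")
    if len(df) != N_POINTS:
        raise ValueError(f"spectra CSV must have {N_POINTS} rows, got {len(df)}")
    ids = [int(c) for c in df.columns if c != "wavelength_nm"]
    return SpectraMatrix(
        absorbance=df[[str(i) for i in ids]].to_numpy(dtype=float).T,
        sample_ids=tuple(ids),
    )
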