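"""Reference dye spectra and optical-density conversion.

Brightfield multispectral quantitation rests on the Beer-Lambert law: a
chromogen of concentration ``c`` with absorbance spectrum ``A(lambda)``
attenuates transmitted light as ``I = I0 * 10**(-c * A)``.  The optical
density ``OD = -log10(I / I0)`` is therefore linear in concentration, which
is what makes per-pixel spectral unmixing a linear problem.

This module holds the three core containers (reference spectrum, intensity
cube, OD cube) and the conversions between them.  Reference spectra are kept
peak-normalized by default so that unmixed concentrations are expressed in
"OD at the dye's absorbance peak" - a unit that is comparable across
reference files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParameterError, RangeError, ShapeError

__all__ = [
    "ReferenceSpectrum",
    "SpectralCube",
    "ODCube",
    "load_reference_spectra",
    "resample_spectrum",
    "reference_matrix",
    "compute_od_cube",
    "builtin_reference_spectra",
    "write_reference_csv",
    "DEFAULT_WAVELENGTHS_NM",
]

#: Default acquisition grid: visible range 420-720 nm in 10 nm steps (31 planes).
DEFAULT_WAVELENGTHS_NM: np.ndarray = np.arange(420.0, 721.0, 10.0)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Absorbance of one dye as a function of wavelength.

    Parameters
    ----------
    dye_name
        Identifier, e.g. ``"NBT/BCIP"`` or ``"methyl_green"``.
    wavelengths
        Strictly increasing wavelengths in nm.
    absorbance
        Non-negative absorbance per unit concentration (unitless OD).
    normalization
        ``"peak_unit"`` (max absorbance exactly 1), ``"area_unit"`` or
        ``"raw"``.
    """

    dye_name: str
    wavelengths: np.ndarray
    absorbance: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ShapeError("wavelengths and absorbance must be 1-D of equal length")
        if wl.size < 2:
            raise FormatError("a reference spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise FormatError(f"wavelengths of {self.dye_name!r} are not strictly increasing")
        if not np.all(np.isfinite(ab)) or np.any(ab < 0):
            raise FormatError(f"absorbance of {self.dye_name!r} must be finite and >= 0")
        if self.normalization == "peak_unit" and not np.isclose(ab.max(), 1.0, rtol=0, atol=1e-12):
            raise FormatError("peak_unit normalization requires max(absorbance) == 1")

    def peak_normalized(self) -> "ReferenceSpectrum":
        """Return a copy scaled so the maximum absorbance is exactly 1."""
        peak = self.absorbance.max()
        if peak <= 0:
            raise FormatError(f"spectrum {self.dye_name!r} is identically zero")
        ab = self.absorbance / peak
        ab[np.argmax(ab)] = 1.0  # guard against round-off on the peak itself
        return replace(self, absorbance=ab, normalization="peak_unit")


@dataclass
class SpectralCube:
    """Transmitted-light intensity stack, one grayscale plane per wavelength.

    ``planes`` has shape ``(n_wavelengths, height, width)`` in detector
    counts.  ``white_reference`` is the blank-field intensity I0, either one
    scalar per plane (shape ``(n_wavelengths,)``) or a full image per plane
    (same shape as ``planes``).
    """

    wavelengths: np.ndarray
    planes: np.ndarray
    white_reference: np.ndarray | None = None
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ShapeError("planes must be 3-D (wavelength, row, column)")
        if self.wavelengths.size != self.planes.shape[0]:
            raise ShapeError("number of planes must equal number of wavelengths")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("cube wavelengths must be strictly increasing")
        if np.any(self.planes < 0):
            raise FormatError("intensity counts must be >= 0")
        if self.white_reference is not None:
            wr = np.asarray(self.white_reference, dtype=float)
            if wr.shape not in (self.planes.shape, (self.planes.shape[0],)):
                raise ShapeError("white_reference must be per-plane scalar or full image")
            if np.any(wr <= 0):
                raise FormatError("white_reference must be positive")
            self.white_reference = wr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.planes.shape


@dataclass
class ODCube:
    """Optical-density stack: ``od[l, y, x] = -log10(I / I0)``, clamped at 0."""

    wavelengths: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[0] != self.wavelengths.size:
            raise ShapeError("od must be 3-D with one plane per wavelength")
        if not np.all(np.isfinite(self.od)):
            raise FormatError("od must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.od.shape


def load_reference_spectra(path: str | Path) -> list[ReferenceSpectrum]:
    """Read reference spectra from CSV (``wavelength_nm, dye1, dye2, ...``).

    Spectra are returned peak-normalized, in the column order of the file.
    Both LF and CRLF line endings are accepted; the header row is mandatory.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise FormatError("reference CSV needs a wavelength column plus >= 1 dye column")
    wl = frame.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise FormatError("reference CSV wavelengths must be strictly increasing")
    spectra = []
    for name in frame.columns[1:]:
        ab = frame[name].to_numpy(dtype=float)
        if np.any(ab < 0) or not np.all(np.isfinite(ab)):
            raise FormatError(f"negative or non-finite absorbance in column {name!r}")
        spectra.append(ReferenceSpectrum(str(name), wl, ab).peak_normalized())
    return spectra


def write_reference_csv(refs: Sequence[ReferenceSpectrum], path: str | Path) -> None:
    """Write spectra sharing one wavelength grid to the CSV convention above."""
    wl = refs[0].wavelengths
    for r in refs[1:]:
        if not np.array_equal(r.wavelengths, wl):
            raise ShapeError("all spectra must share one wavelength grid to be written together")
    frame = pd.DataFrame({"wavelength_nm": wl})
    for r in refs:
        frame[r.dye_name] = r.absorbance
    frame.to_csv(path, index=False)


def resample_spectrum(ref: ReferenceSpectrum, wavelengths: Sequence[float]) -> ReferenceSpectrum:
    """Linearly interpolate a reference spectrum onto a new wavelength grid.

    Raises :class:`RangeError` on any extrapolation request.  A
    ``peak_unit`` spectrum is re-normalized after interpolation so the
    contract ``max == 1`` survives resampling.
    """
    target = np.asarray(wavelengths, dtype=float)
    if target.ndim != 1 or target.size < 2 or not np.all(np.diff(target) > 0):
        raise ParameterError("target wavelengths must be 1-D, strictly increasing, length >= 2")
    lo, hi = ref.wavelengths[0], ref.wavelengths[-1]
    if target[0] < lo or target[-1] > hi:
        raise RangeError(
            f"requested {target[0]:g}-{target[-1]:g} nm outside reference support "
            f"{lo:g}-{hi:g} nm for dye {ref.dye_name!r}"
        )
    ab = np.interp(target, ref.wavelengths, ref.absorbance)
    out = ReferenceSpectrum(ref.dye_name, target, ab, normalization="raw")
    if ref.normalization == "peak_unit":
        out = out.peak_normalized()
    return out


def reference_matrix(refs: Sequence[ReferenceSpectrum], wavelengths: Sequence[float] | None = None) -> np.ndarray:
    """Stack reference spectra into the (n_wavelengths, n_dyes) design matrix.

    If ``wavelengths`` is given, each spectrum is resampled onto that grid
    first; otherwise all spectra must already share one grid.
    """
    if wavelengths is not None:
        refs = [resample_spectrum(r, wavelengths) for r in refs]
    wl = refs[0].wavelengths
    for r in refs[1:]:
        if not np.array_equal(r.wavelengths, wl):
            raise ShapeError("reference spectra are on different wavelength grids")
    return np.column_stack([r.absorbance for r in refs])


def estimate_white_reference(planes: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-plane blank-field estimate from the brightest pixels of each plane.

    Fallback for cubes acquired without an explicit blank field: in sparsely
    stained tissue the top-percentile intensity of each plane approximates
    unattenuated illumination.
    """
    return np.percentile(planes.reshape(planes.shape[0], -1), percentile, axis=1)


def compute_od_cube(cube: SpectralCube, floor_counts: float = 1.0) -> ODCube:
    """Convert a transmitted-intensity cube to optical density.

    ``od = -log10(max(I, floor_counts) / I0)`` clamped below at 0.  The floor
    guards against ``log(0)`` on dead pixels; the clamp discards negative OD
    from specular or noise pixels brighter than the blank field, since dye
    concentrations are physically non-negative.
    """
    if floor_counts < 1:
        raise ParameterError("floor_counts must be >= 1")
    if cube.white_reference is None:
        raise ConfigurationError(
            "cube has no white_reference; supply one or use estimate_white_reference()"
        )
    i0 = cube.white_reference
    if i0.ndim == 1:
        i0 = i0[:, None, None]
    od = -np.log10(np.maximum(cube.planes, floor_counts) / i0)
    np.clip(od, 0.0, None, out=od)
    return ODCube(cube.wavelengths, od)


def builtin_reference_spectra(wavelengths: Sequence[float] | None = None) -> list[ReferenceSpectrum]:
    """Synthetic reference absorbance spectra for NBT/BCIP and methyl green.

    These are smooth Gaussian-mixture models, not measured instrument
    references: the NBT/BCIP formazan precipitate is modeled as a broad
    visible band peaking near 585 nm, methyl green as a narrower band at
    632 nm plus a weak blue shoulder.  They reproduce the qualitative shape
    and overlap of the real chromogens well enough to exercise every stage
    of the pipeline, and are returned peak-normalized.
    """
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths, dtype=float)

    def gauss(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((wl - center) / width) ** 2)

    nbt = gauss(585.0, 72.0)
    mg = gauss(632.0, 28.0) + 0.35 * gauss(455.0, 45.0)
    return [
        ReferenceSpectrum("NBT/BCIP", wl, nbt).peak_normalized(),
        ReferenceSpectrum("methyl_green", wl, mg).peak_normalized(),
    ]
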