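"""Per-pixel non-negative spectral unmixing.

Each pixel's OD spectrum is modeled as a non-negative combination of the
reference dye spectra: ``od_pixel ~ A @ c`` with ``c >= 0``, where the
columns of ``A`` are the (peak-normalized) reference absorbances on the
cube's wavelength grid.  The solver is exact non-negative least squares:

* all pixels are first solved unconstrained via the pseudoinverse (a single
  matrix product over the whole image);
* pixels whose unconstrained solution is already non-negative are done -
  on clean data that is nearly all of them;
* the remainder are re-solved on the active-set boundary.  For the two-dye
  case every boundary (one dye clamped to zero) has a closed form, so the
  fix-up is vectorized; with more dyes it falls back to
  ``scipy.optimize.nnls`` per pixel.

Concentrations are in OD units at the peak-normalized reference: ``c_j`` is
the OD dye ``j`` alone would produce at its absorbance peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import DegeneracyError, ShapeError
from .spectra import ODCube, ReferenceSpectrum, reference_matrix

__all__ = ["ConcentrationMaps", "unmix_cube", "unmixing_quality"]

#: Pixels whose summed OD over all planes falls below this are assigned
#: c = 0 without solving (numerical hygiene on empty background).
MIN_TOTAL_OD: float = 1e-4


@dataclass
class ConcentrationMaps:
    """Unmixed per-dye amounts plus the per-pixel RMS residual.

    ``maps`` has shape ``(n_dyes, height, width)`` in the order of
    ``dye_names`` (which matches the reference list used for unmixing).
    """

    dye_names: tuple[str, ...]
    maps: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.dye_names):
            raise ShapeError("maps must be (n_dyes, height, width)")
        if self.residual.shape != self.maps.shape[1:]:
            raise ShapeError("residual shape must match image shape")
        if np.any(self.maps < 0) or not np.all(np.isfinite(self.maps)):
            raise ShapeError("concentration maps must be finite and >= 0")
        if np.any(self.residual < 0):
            raise ShapeError("residual must be >= 0")

    def __getitem__(self, dye_name: str) -> np.ndarray:
        return self.maps[self.dye_names.index(dye_name)]


def _check_rank(A: np.ndarray, refs: Sequence[ReferenceSpectrum]) -> None:
    """Reject collinear reference sets, naming the offending pair."""
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        idx = int(np.argmin(norms))
        raise DegeneracyError(f"reference spectrum {refs[idx].dye_name!r} is identically zero")
    unit = A / norms
    k = A.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if abs(float(unit[:, i] @ unit[:, j])) > 1.0 - 1e-10:
                raise DegeneracyError(
                    f"reference spectra {refs[i].dye_name!r} and {refs[j].dye_name!r} "
                    "are collinear; unmixing is degenerate"
                )
    if np.linalg.matrix_rank(A) < k:
        raise DegeneracyError("reference matrix is rank-deficient")


def _nnls_two_dye(A: np.ndarray, B: np.ndarray, C: np.ndarray, bad: np.ndarray) -> None:
    """Closed-form boundary NNLS for K=2, applied in place to columns ``bad``.

    If the unconstrained optimum has a negative coordinate, the constrained
    optimum lies on a boundary c_i = 0; evaluate both boundaries and keep
    the one with the smaller residual.
    """
    a0, a1 = A[:, 0], A[:, 1]
    Bb = B[:, bad]
    c0 = np.clip(a0 @ Bb / (a0 @ a0), 0.0, None)
    c1 = np.clip(a1 @ Bb / (a1 @ a1), 0.0, None)
    r0 = np.sum((np.outer(a0, c0) - Bb) ** 2, axis=0)
    r1 = np.sum((np.outer(a1, c1) - Bb) ** 2, axis=0)
    use0 = r0 <= r1
    out = np.zeros((2, Bb.shape[1]))
    out[0, use0] = c0[use0]
    out[1, ~use0] = c1[~use0]
    C[:, bad] = out


def unmix_cube(od: ODCube, refs: Sequence[ReferenceSpectrum]) -> ConcentrationMaps:
    """Decompose every pixel's OD spectrum into non-negative dye amounts.

    Parameters
    ----------
    od
        Optical-density cube.
    refs
        Reference spectra, already on (or resampled to) ``od.wavelengths``.

    Returns
    -------
    ConcentrationMaps
        Per-dye amount maps (same dye order as ``refs``) and the per-pixel
        root-mean-square of the unexplained OD.
    """
    A = reference_matrix(refs, od.wavelengths)
    _check_rank(A, refs)
    L, H, W = od.shape
    K = A.shape[1]
    B = od.od.reshape(L, H * W)

    C = np.zeros((K, H * W))
    active = B.sum(axis=0) >= MIN_TOTAL_OD
    if active.any():
        C[:, active] = np.linalg.pinv(A) @ B[:, active]
        bad = active & np.any(C < -1e-12, axis=0)
        if bad.any():
            if K == 2:
                _nnls_two_dye(A, B, C, bad)
            else:
                for j in np.flatnonzero(bad):
                    C[:, j] = nnls(A, B[:, j])[0]
        np.clip(C, 0.0, None, out=C)

    resid = np.sqrt(np.mean((A @ C - B) ** 2, axis=0))
    return ConcentrationMaps(
        dye_names=tuple(r.dye_name for r in refs),
        maps=C.reshape(K, H, W),
        residual=resid.reshape(H, W),
    )


def unmixing_quality(
    maps: ConcentrationMaps,
    od: ODCube | None = None,
    residual_threshold: float = 0.05,
) -> dict[str, float]:
    """Deterministic QC summary of the unmixing residual map.

    Returns the mean and max per-pixel RMS residual and the fraction of
    pixels whose residual exceeds ``residual_threshold`` (OD units).  If the
    source ``od`` cube is supplied its shape is checked against the maps.
    """
    if od is not None and od.shape[1:] != maps.maps.shape[1:]:
        raise ShapeError("OD cube and concentration maps have different image shapes")
    r = maps.residual
    return {
        "mean_residual": float(r.mean()),
        "max_residual": float(r.max()),
        "fraction_above_threshold": float(np.mean(r > residual_threshold)),
    }
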