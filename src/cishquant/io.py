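"""File-format glue: TIFF image cubes with JSON sidecars, masks, CSV tables.

A spectral cube on disk is a multi-page TIFF (one 16-bit grayscale page per
wavelength) plus a JSON sidecar of the same stem carrying
``wavelengths_nm``, the per-plane white reference ``i0`` and any simulation
provenance.  Masks are 8-bit TIFFs (0/255).  All tables are UTF-8 CSV with
a header row, '.' decimal separator and empty fields for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .errors import ConfigurationError, FormatError
from .spectra import SpectralCube
from .unmixing import ConcentrationMaps

__all__ = [
    "write_cube",
    "read_cube",
    "write_mask",
    "read_mask",
    "write_concentration_maps",
    "sidecar_path",
]


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_cube(cube: SpectralCube, tiff_path: str | Path, extra: Mapping | None = None) -> None:
    """Write a cube as uint16 multi-page TIFF plus its JSON sidecar.

    Counts are rounded and clipped to the uint16 range; the exact float
    white reference is preserved in the sidecar.
    """
    tiff_path = Path(tiff_path)
    pages = np.clip(np.rint(cube.planes), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    if cube.white_reference is None:
        raise ConfigurationError("cube must carry a white_reference to be written")
    meta = {
        "wavelengths_nm": [float(w) for w in cube.wavelengths],
        "i0": np.asarray(cube.white_reference).tolist(),
    }
    if extra:
        meta.update(extra)
    sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_cube(tiff_path: str | Path) -> SpectralCube:
    """Read a cube and its sidecar back into a :class:`SpectralCube`."""
    tiff_path = Path(tiff_path)
    side = sidecar_path(tiff_path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar for {tiff_path.name}")
    try:
        meta = json.loads(side.read_text())
        planes = tifffile.imread(tiff_path)
    except (json.JSONDecodeError, OSError, ValueError) as exc:
        raise FormatError(f"unreadable cube {tiff_path.name}: {exc}") from exc
    planes = np.asarray(planes, dtype=float)
    if planes.ndim == 2:
        planes = planes[None]
    wl = np.asarray(meta["wavelengths_nm"], dtype=float)
    i0 = np.asarray(meta["i0"], dtype=float)
    return SpectralCube(wl, planes, white_reference=i0)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit TIFF (255 = true)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)),
                     photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask TIFF; any nonzero pixel is true."""
    try:
        return np.asarray(tifffile.imread(Path(path))) > 0
    except (OSError, ValueError) as exc:
        raise FormatError(f"unreadable mask {Path(path).name}: {exc}") from exc


def write_concentration_maps(maps: ConcentrationMaps, outdir: str | Path, stem: str) -> list[Path]:
    """Write one 32-bit float TIFF per dye plus the residual map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, plane in zip(maps.dye_names, maps.maps):
        safe = name.replace("/", "_").replace(" ", "_")
        p = outdir / f"{stem}_{safe}.tif"
        tifffile.imwrite(p, plane.astype(np.float32), photometric="minisblack")
        written.append(p)
    p = outdir / f"{stem}_residual.tif"
    tifffile.imwrite(p, maps.residual.astype(np.float32), photometric="minisblack")
    written.append(p)
    return written
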