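"""Synthetic cohort and image-cube generator.

No slide images accompany the study design this package targets, so every
downstream stage is validated against simulated data with known ground
truth.  The generator reproduces the study's statistical structure:

* six groups - three colorectal lesion stages (LGIN, HGIN, CA) and their
  paralesional normal controls (LGIN-N, HGIN-N, CA-N) - with sample counts
  13/12/11/10/10/9 and three technical replicates per sample;
* a monotone increase of mean cytoplasmic NBT/BCIP optical density from the
  normal controls through LGIN and HGIN to carcinoma, with all group means
  inside the observed OD range [0.20825, 0.9455];
* two-dye Beer-Lambert mixing (NBT/BCIP in cytoplasm and, via partial
  co-localization, in nuclei; methyl green in nuclei) with optional Poisson
  shot noise on the transmitted counts.

Randomness is fully reproducible: every stochastic function takes a seed and
cohort simulation derives one independent stream per sample-replicate from
it, so cubes can be regenerated lazily and in any order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError
from .quantitation import default_grade_scale, grade_code, grade_od
from .spectra import (
    DEFAULT_WAVELENGTHS_NM,
    ODCube,
    ReferenceSpectrum,
    SpectralCube,
    reference_matrix,
)

__all__ = [
    "GROUP_LABELS",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_EFFECT_MEANS",
    "OD_RANGE",
    "GroundTruthScene",
    "CohortDesign",
    "SceneParams",
    "CohortSimulation",
    "make_default_design",
    "simulate_scene",
    "render_cube",
    "draw_sample_effects",
    "simulate_cohort",
]

#: The six study groups: lesion stages and their paralesional normal controls.
GROUP_LABELS: tuple[str, ...] = ("CA", "CA-N", "HGIN", "HGIN-N", "LGIN", "LGIN-N")

#: Published cohort sizes (34 lesion + 31 control samples).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "CA": 13, "CA-N": 12, "HGIN": 11, "HGIN-N": 10, "LGIN": 10, "LGIN-N": 9,
}

#: Observed min/max mean optical density across the study's samples.
OD_RANGE: tuple[float, float] = (0.20825, 0.9455)

#: Default group-level mean cytoplasmic OD.  Monotone non-decreasing along
#: LGIN-N <= LGIN <= HGIN <= CA, all within OD_RANGE; the control-vs-lesion
#: gaps give high power for the primary CA vs CA-N contrast at n = 13 vs 12.
DEFAULT_EFFECT_MEANS: dict[str, float] = {
    "LGIN-N": 0.30, "HGIN-N": 0.33, "CA-N": 0.36,
    "LGIN": 0.45, "HGIN": 0.60, "CA": 0.75,
}

#: Default between-sample SD of the group-level effect distribution (OD units).
DEFAULT_EFFECT_SD: float = 0.08

#: Default replicate-level multiplicative jitter (log-normal sigma).
DEFAULT_REPLICATE_SIGMA: float = 0.05


@dataclass
class GroundTruthScene:
    """A simulated stained-tissue field with known dye amounts.

    ``conc_nbt`` / ``conc_mg`` are per-pixel dye amounts in OD units (at the
    peak-normalized reference), zero outside the stained compartments.
    """

    conc_nbt: np.ndarray
    conc_mg: np.ndarray
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.conc_nbt.shape
        for name in ("conc_mg", "nucleus_mask", "cytoplasm_mask", "roi_mask"):
            if getattr(self, name).shape != shape:
                raise ShapeError(f"{name} shape differs from conc_nbt")
        for name in ("conc_nbt", "conc_mg"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ParameterError(f"{name} must be finite and >= 0")
        if np.any(self.nucleus_mask & ~self.roi_mask) or np.any(self.cytoplasm_mask & ~self.roi_mask):
            raise ParameterError("compartment masks must lie inside roi_mask")

    @property
    def height(self) -> int:
        return self.conc_nbt.shape[0]

    @property
    def width(self) -> int:
        return self.conc_nbt.shape[1]


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: group sizes, replicates, and per-group effect profile.

    ``effect_profile`` maps each group label to ``(mean_od, sd_od)``: the
    group-level mean cytoplasmic NBT/BCIP optical density and the
    between-sample standard deviation.
    """

    groups: tuple[tuple[str, int], ...]
    replicates_per_sample: int
    effect_profile: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.replicates_per_sample < 1:
            raise ParameterError("replicates_per_sample must be >= 1")
        for label, n in self.groups:
            if n < 1:
                raise ParameterError(f"group {label!r} must have >= 1 sample")
            if label not in self.effect_profile:
                raise ParameterError(f"effect_profile missing group {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.groups)

    @property
    def n_lesion_samples(self) -> int:
        return sum(n for label, n in self.groups if not label.endswith("-N"))

    @property
    def n_control_samples(self) -> int:
        return sum(n for label, n in self.groups if label.endswith("-N"))

    @property
    def total_samples(self) -> int:
        return sum(n for _, n in self.groups)

    @property
    def total_measurements(self) -> int:
        return self.total_samples * self.replicates_per_sample


def make_default_design() -> CohortDesign:
    """The published cohort: 34 lesion + 31 control samples in six groups,
    three replicates each, with the default monotone effect profile."""
    return CohortDesign(
        groups=tuple((label, DEFAULT_GROUP_SIZES[label]) for label in GROUP_LABELS),
        replicates_per_sample=3,
        effect_profile={label: (DEFAULT_EFFECT_MEANS[label], DEFAULT_EFFECT_SD) for label in GROUP_LABELS},
    )


def _texture(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Mean-one multiplicative log-normal texture (ones when sigma == 0)."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def simulate_scene(
    height: int,
    width: int,
    n_cells: int,
    mean_cyto_od: float,
    mean_nuc_od: float,
    overlap_fraction: float,
    seed: int,
    cell_radius: float | None = None,
    texture_sigma: float = 0.10,
) -> GroundTruthScene:
    """Place cells (methyl-green nuclei inside NBT/BCIP cytoplasmic discs).

    A fraction ``overlap_fraction`` of nuclear pixels additionally carries
    NBT/BCIP, modeling hybridization signal co-localized with the nuclear
    counterstain.  Per-pixel dye amounts are the stated means modulated by a
    mean-one log-normal texture (``texture_sigma = 0`` gives exact means).
    The ROI covers the whole field.
    """
    if height < 32 or width < 32:
        raise ParameterError("scene dimensions must be >= 32 pixels")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ParameterError("overlap_fraction must lie in [0, 1]")
    if mean_cyto_od < 0 or mean_nuc_od < 0:
        raise ParameterError("mean OD values must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    if cell_radius is None:
        cell_radius = max(4.0, min(height, width) / 14.0)

    yy, xx = np.mgrid[0:height, 0:width]
    cyto_disc = np.zeros((height, width), dtype=bool)
    nucleus = np.zeros((height, width), dtype=bool)
    for _ in range(n_cells):
        r = cell_radius * rng.uniform(0.8, 1.2)
        cy = rng.uniform(r, height - r)
        cx = rng.uniform(r, width - r)
        dy, dx = yy - cy, xx - cx
        cyto_disc |= dy**2 + dx**2 <= r**2
        # rotated ellipse nucleus inside the disc
        theta = rng.uniform(0, np.pi)
        a = 0.55 * r * rng.uniform(0.85, 1.15)
        b = 0.40 * r * rng.uniform(0.85, 1.15)
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        nucleus |= (u / a) ** 2 + (v / b) ** 2 <= 1.0

    nucleus &= cyto_disc
    cytoplasm = cyto_disc & ~nucleus

    conc_nbt = np.zeros((height, width))
    conc_mg = np.zeros((height, width))
    cyto_idx = np.flatnonzero(cytoplasm)
    nuc_idx = np.flatnonzero(nucleus)
    conc_nbt.flat[cyto_idx] = mean_cyto_od * _texture(rng, cyto_idx.size, texture_sigma)
    conc_mg.flat[nuc_idx] = mean_nuc_od * _texture(rng, nuc_idx.size, texture_sigma)
    if nuc_idx.size:
        k = int(round(overlap_fraction * nuc_idx.size))
        if k:
            sel = rng.choice(nuc_idx, size=k, replace=False)
            conc_nbt.flat[sel] = mean_cyto_od * _texture(rng, k, texture_sigma)

    roi = np.ones((height, width), dtype=bool)
    return GroundTruthScene(conc_nbt, conc_mg, nucleus, cytoplasm, roi)


def scene_od_cube(scene: GroundTruthScene, refs: Sequence[ReferenceSpectrum],
                  wavelengths: Sequence[float] | None = None) -> ODCube:
    """Noise-free OD cube of a scene: ``od = c_nbt*A_nbt + c_mg*A_mg``."""
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths, dtype=float)
    A = reference_matrix(refs, wl)
    nbt_col, mg_col = _dye_columns(refs)
    od = (A[:, nbt_col, None, None] * scene.conc_nbt[None]
          + A[:, mg_col, None, None] * scene.conc_mg[None])
    return ODCube(wl, od)


def _dye_columns(refs: Sequence[ReferenceSpectrum]) -> tuple[int, int]:
    """Locate the NBT/BCIP and methyl green columns by dye name."""
    nbt = mg = None
    for i, r in enumerate(refs):
        name = r.dye_name.lower()
        if "nbt" in name or "bcip" in name:
            nbt = i
        elif "methyl" in name or name == "mg":
            mg = i
    if nbt is None or mg is None:
        raise ParameterError("references must include NBT/BCIP and methyl green spectra")
    return nbt, mg


def render_cube(
    scene: GroundTruthScene,
    refs: Sequence[ReferenceSpectrum],
    wavelengths: Sequence[float] | None = None,
    i0: float = 4096.0,
    noise_model: str = "none",
    seed: int = 0,
) -> SpectralCube:
    """Beer-Lambert forward model: transmitted counts from a ground-truth scene.

    ``I(lambda) = i0 * 10**(-(c_nbt*A_nbt(lambda) + c_mg*A_mg(lambda)))``,
    optionally Poisson-sampled to emulate shot noise of a cooled monochrome
    CCD.  Without noise, intensity never exceeds ``i0``.
    """
    if i0 <= 0:
        raise ParameterError("i0 must be positive")
    if noise_model not in ("none", "poisson"):
        raise ParameterError(f"unknown noise_model {noise_model!r}")
    odc = scene_od_cube(scene, refs, wavelengths)
    planes = i0 * 10.0 ** (-odc.od)
    if noise_model == "poisson":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E11]))
        planes = rng.poisson(planes).astype(float)
    white = np.full(odc.wavelengths.size, float(i0))
    return SpectralCube(odc.wavelengths, planes, white_reference=white)


@dataclass(frozen=True)
class SceneParams:
    """Geometry/noise settings shared by every simulated cube of a cohort."""

    height: int = 128
    width: int = 128
    n_cells: int = 40
    mean_nuc_od: float = 0.50
    overlap_fraction: float = 0.30
    texture_sigma: float = 0.10
    i0: float = 4096.0
    noise_model: str = "poisson"
    wavelengths: tuple[float, ...] = tuple(DEFAULT_WAVELENGTHS_NM)


def draw_sample_effects(
    design: CohortDesign,
    seed: int,
    replicate_sigma: float = DEFAULT_REPLICATE_SIGMA,
) -> pd.DataFrame:
    """Draw the cohort's true per-sample and per-replicate cytoplasmic ODs.

    Sample-level means come from the group's normal distribution truncated
    at zero; replicate values apply independent multiplicative log-normal
    jitter (technical variance of the triplicate measurements).  A simulated
    visual grade per sample is included: the four-tier grade of the true OD
    randomly blurred by one tier half the time, emulating the poor
    discrimination of grading by eye.

    Returns one row per (sample, replicate):
    ``sample_id, group, replicate, sample_od, replicate_od, visual_grade``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC040]))
    scale = default_grade_scale()
    rows = []
    for label, n in design.groups:
        mean, sd = design.effect_profile[label]
        for s in range(n):
            sample_od = -1.0
            while sample_od < 0:  # truncate the group-level normal at 0
                sample_od = rng.normal(mean, sd)
            sample_id = f"{label}-{s + 1:02d}"
            code = grade_code(grade_od(sample_od, scale))
            visual = int(np.clip(code + rng.choice([-1, 0, 1], p=[0.25, 0.5, 0.25]), 1, 4))
            for rep in range(design.replicates_per_sample):
                jitter = np.exp(rng.normal(-0.5 * replicate_sigma**2, replicate_sigma))
                rows.append({
                    "sample_id": sample_id,
                    "group": label,
                    "replicate": rep + 1,
                    "sample_od": sample_od,
                    "replicate_od": sample_od * jitter,
                    "visual_grade": visual,
                })
    return pd.DataFrame(rows)


@dataclass
class CohortSimulation:
    """A simulated cohort: manifest, ground truth, and lazily rendered cubes.

    Cubes are regenerated on demand from per-replicate seeds, so iterating
    never holds more than one cube in memory and any replicate can be
    re-rendered independently and deterministically.
    """

    design: CohortDesign
    scene_params: SceneParams
    seed: int
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    refs: tuple[ReferenceSpectrum, ...]

    def render_one(self, row: Mapping) -> tuple[GroundTruthScene, SpectralCube]:
        """Re-render the scene and cube for one manifest row."""
        p = self.scene_params
        scene_seed = int(row["scene_seed"])
        scene = simulate_scene(
            p.height, p.width, p.n_cells,
            mean_cyto_od=float(row["replicate_od"]),
            mean_nuc_od=p.mean_nuc_od,
            overlap_fraction=p.overlap_fraction,
            seed=scene_seed,
            texture_sigma=p.texture_sigma,
        )
        cube = render_cube(scene, self.refs, np.asarray(p.wavelengths),
                           i0=p.i0, noise_model=p.noise_model, seed=scene_seed + 1)
        return scene, cube

    def iter_cubes(self) -> Iterator[tuple[pd.Series, GroundTruthScene, SpectralCube]]:
        for _, row in self.manifest.iterrows():
            scene, cube = self.render_one(row)
            yield row, scene, cube

    def write(self, outdir) -> "Path":
        """Write cubes, a shared whole-field ROI mask, manifest and ground
        truth to ``outdir``; returns the manifest CSV path."""
        from pathlib import Path

        from .io import write_cube, write_mask

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        roi_path = outdir / "roi.tif"
        write_mask(np.ones((self.scene_params.height, self.scene_params.width), dtype=bool),
                   roi_path)
        for row, _scene, cube in self.iter_cubes():
            write_cube(cube, outdir / row["cube_path"],
                       extra={"seed": int(row["scene_seed"]), "sample_id": row["sample_id"]})
        manifest = self.manifest.copy()
        manifest["roi_path"] = roi_path.name
        manifest_path = outdir / "manifest.csv"
        manifest.to_csv(manifest_path, index=False)
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        return manifest_path


def simulate_cohort(
    design: CohortDesign | None = None,
    scene_params: SceneParams | None = None,
    seed: int = 0,
    refs: Sequence[ReferenceSpectrum] | None = None,
) -> CohortSimulation:
    """Simulate the full cohort: one cube per sample-replicate.

    The manifest carries sample id, group, replicate index and the seed of
    each cube's random stream; the ground-truth table carries the true
    sample- and replicate-level ODs for recovery tests.
    """
    from .spectra import builtin_reference_spectra

    design = design or make_default_design()
    scene_params = scene_params or SceneParams()
    refs = tuple(refs) if refs is not None else tuple(builtin_reference_spectra(np.asarray(scene_params.wavelengths)))

    effects = draw_sample_effects(design, seed)
    # one independent, order-insensitive scene seed per sample-replicate
    base = np.random.SeedSequence([int(seed), 0x5CEE])
    children = base.generate_state(len(effects) + 1, dtype=np.uint32)[1:]
    manifest = effects.copy()
    manifest["scene_seed"] = children.astype(np.int64)
    manifest["cube_path"] = [
        f"{r.sample_id}_rep{r.replicate}.tif" for r in manifest.itertuples()
    ]
    ground_truth = effects.copy()
    return CohortSimulation(design, scene_params, int(seed), manifest, ground_truth, refs)
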