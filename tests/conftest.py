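import numpy as np
import pytest

from cishquant.spectra import builtin_reference_spectra
from cishquant.synthetic import SceneParams, make_default_design, simulate_cohort, simulate_scene


@pytest.fixture(scope="session")
def refs():
    return builtin_reference_spectra()


@pytest.fixture(scope="session")
def default_scene():
    return simulate_scene(64, 64, n_cells=12, mean_cyto_od=0.5, mean_nuc_od=0.5,
                          overlap_fraction=0.3, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A reduced two-lesion-stage cohort on small scenes for pipeline tests."""
    from cishquant.synthetic import CohortDesign

    design = CohortDesign(
        groups=(("CA", 3), ("CA-N", 3)),
        replicates_per_sample=2,
        effect_profile={"CA": (0.75, 0.08), "CA-N": (0.36, 0.08)},
    )
    params = SceneParams(height=48, width=48, n_cells=8)
    return simulate_cohort(design, params, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    tiny_cohort.write(outdir)
    return outdir
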