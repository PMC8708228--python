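import numpy as np
import pytest

from mandiblefit.synthetic import (
    build_template,
    sample_cohort,
    training_cohort_config,
)
from mandiblefit.study import build_region_models


@pytest.fixture(scope="session")
def template():
    return build_template((40, 8))


@pytest.fixture(scope="session")
def cohort_and_truth():
    """Small training-style cohort with a dominant allometric mode."""
    cfg = training_cohort_config(seed=11, noise_sd=0.05)
    cfg.n_specimens = 40
    cfg.demographics = None
    cfg.template_resolution = (40, 8)
    return sample_cohort(cfg)


@pytest.fixture(scope="session")
def region_models(cohort_and_truth):
    cohort, truth = cohort_and_truth
    return build_region_models(cohort, truth.template)


@pytest.fixture(scope="session")
def small_study(region_models, cohort_and_truth):
    """Fit results of all 11 plate designs on two noiseless (hence
    bilaterally symmetric) test specimens."""
    from mandiblefit.plate_design import design_plate_family
    from mandiblefit.plate_fit import run_study
    from mandiblefit.synthetic import SyntheticCohortConfig

    _, truth = cohort_and_truth
    plates = design_plate_family(region_models)
    cfg = SyntheticCohortConfig(
        n_specimens=2, seed=33, noise_sd=0.0, template_resolution=(40, 8)
    )
    test_cohort, _ = sample_cohort(cfg)
    results = run_study(plates, test_cohort, truth.template)
    return results, test_cohort


@pytest.fixture
def cube_mesh():
    """Unit cube as an indexed mesh (8 vertices, 12 consistently wound faces)."""
    from mandiblefit.mesh import TriangleMesh

    v = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0, outward -x
            [4, 6, 7], [4, 7, 5],  # x = 1
            [0, 4, 5], [0, 5, 1],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ]
    )
    mesh = TriangleMesh(v, f)
    mesh.validate(strict=True)
    return mesh
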