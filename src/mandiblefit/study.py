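"""End-to-end study driver: cohorts -> shape models -> plates -> fit report.

Chains the full pipeline at the study's design scale (127 training
specimens, 50 test specimens, 20 virtual tests per specimen = 1000 tests)
on synthetic cohorts, so the whole computation is reproducible from a
single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic import (
    Template,
    CorrespondedCohort,
    sample_cohort,
    training_cohort_config,
    test_cohort_config,
)
from .shape_model import RegionDefinition, RegionShapeModel
from .plate_design import design_plate_family
from .plate_fit import FitConfig, run_study, results_to_frame
from .reporting import CohortFitSummary, summarize

__all__ = ["StudyOutput", "build_region_models", "run_virtual_study"]

#: plate type -> (region name, model side); bilateral plates are designed on
#: the left side and mirrored at test time
MODEL_REGIONS = {
    "condyle": ("condyle", "left"),
    "body": ("body", "left"),
    "angle": ("angle", "left"),
    "symphysis": ("symphysis", "midline"),
}


def build_region_models(cohort: CorrespondedCohort, template: Template) -> dict:
    """Fit the four per-region shape models used for plate design."""
    models = {}
    for ptype, (region_name, side) in MODEL_REGIONS.items():
        region = RegionDefinition.from_template(template, region_name, side)
        models[ptype] = RegionShapeModel.build(cohort, region, template)
    return models


@dataclass
class StudyOutput:
    template: Template
    training: CorrespondedCohort
    testing: CorrespondedCohort
    models: dict
    plates: list
    results: list
    frame: pd.DataFrame
    summary: CohortFitSummary


def run_virtual_study(
    seed: int = 0,
    n_train: int = 127,
    n_test: int = 50,
    noise_sd: float = 0.05,
    mode_scale: float = 1.0,
    sampling_step: float = 1.0,
    fit_config: FitConfig = None,
) -> StudyOutput:
    """Run the complete virtual study.

    ``mode_scale`` multiplies every mode standard deviation in *both*
    cohorts (used to probe how cohort shape variance drives fit rates);
    the training and test cohorts are drawn with independent sub-seeds.
    """
    fit_config = fit_config or FitConfig()
    sds = tuple(s * mode_scale for s in (2.0, 1.0, 0.5))
    train_cfg = training_cohort_config(seed=2 * seed, noise_sd=noise_sd, mode_sds=sds)
    test_cfg = test_cohort_config(seed=2 * seed + 1, noise_sd=noise_sd, mode_sds=sds)
    if n_train != 127:
        train_cfg.n_specimens = n_train
        train_cfg.demographics = None
    if n_test != 50:
        test_cfg.n_specimens = n_test
        test_cfg.demographics = None
    training, train_truth = sample_cohort(train_cfg)
    testing, _ = sample_cohort(test_cfg)
    template = train_truth.template
    models = build_region_models(training, template)
    plates = design_plate_family(models, sampling_step=sampling_step)
    results = run_study(plates, testing, template, fit_config)
    frame = results_to_frame(results, testing.metadata)
    return StudyOutput(
        template, training, testing, models, plates, results, frame, summarize(frame)
    )
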