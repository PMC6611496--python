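"""End-to-end orchestration of the study pipeline.

Chains the stages the CLI exposes — synthetic simulation, cohort
preparation (filters, split, target engineering, normalization), model
training (SVM and MLNN ensemble), per-eye error evaluation and the report —
as plain functions over DataFrames, so the same code path serves the CLI,
the tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import cohort as ch
from . import evaluation as ev
from .config import PipelineConfig, substream
from .models import (
    MlnnEnsemble,
    SvmModel,
    fit_mlnn_em,
    fit_svm_rm,
    predict_iol,
)

__all__ = ["PreparedData", "prepare", "train", "evaluate", "run_all"]


@dataclass
class PreparedData:
    """Output of the preparation stage."""

    filtered: pd.DataFrame              # full cohort with exclusion reasons
    selection: pd.DataFrame             # retained selection cases + derived targets
    verification: pd.DataFrame          # retained verification cases + derived targets
    selection_normed: pd.DataFrame      # normalized predictors + target
    normalizer: ch.MinMaxNormalizer
    out_of_range: pd.DataFrame          # verification cases cleared as out of range

    @property
    def exclusion_report(self) -> pd.DataFrame:
        return ch.exclusion_report(self.filtered)


def prepare(cohort: pd.DataFrame, config: PipelineConfig) -> PreparedData:
    """Filters, split, vergence target engineering and normalization.

    The selection set defines the normalization ranges; verification cases
    with any predictor outside those ranges are cleared before evaluation.
    """
    config = config.with_seeds()
    filtered = ch.run_filter_chain(cohort, config.filters)
    rng = substream(config.master_seed, "split")
    selection, verification = ch.split_cohort(
        filtered, config.selection_fraction, rng
    )
    selection = ch.derive_targets(selection, config.optics)
    verification = ch.derive_targets(verification, config.optics)
    normed, normalizer = ch.build_training_table(selection, config.optics)
    kept, removed = ch.clear_out_of_range(verification, normalizer)
    return PreparedData(
        filtered=filtered,
        selection=selection,
        verification=kept,
        selection_normed=normed,
        normalizer=normalizer,
        out_of_range=removed,
    )


def train(
    prepared: PreparedData, config: PipelineConfig
) -> Dict[str, SvmModel | MlnnEnsemble]:
    """Fit SVM-RM and MLNN-EM on the normalized selection table."""
    config = config.with_seeds()
    return {
        "SVM-RM": fit_svm_rm(prepared.selection_normed, config.svm),
        "MLNN-EM": fit_mlnn_em(prepared.selection_normed, config.mlnn),
    }


def evaluate(
    prepared: PreparedData,
    models: Mapping[str, SvmModel | MlnnEnsemble],
) -> pd.DataFrame:
    """Per-eye signed refractive errors on the verification set.

    Returns the error table with a CR column (achieved clinical refraction
    relative to the emmetropic target) and one back-calculated column per
    model.
    """
    predictions = {
        name: predict_iol(model, prepared.verification, prepared.normalizer)
        for name, model in models.items()
    }
    return ev.refractive_error_table(prepared.verification, predictions)


def run_all(
    config: PipelineConfig, cohort: Optional[pd.DataFrame] = None
) -> Dict[str, object]:
    """simulate (unless a cohort is given) -> prepare -> train -> evaluate -> report."""
    from .synthetic import generate_cohort
    import dataclasses

    config = config.with_seeds()
    truth = None
    if cohort is None:
        cohort, truth = generate_cohort(config.synthetic)
    prepared = prepare(cohort, config)
    models = train(prepared, config)
    errors = evaluate(prepared, models)
    report = ev.evaluation_report(errors)
    return {
        "cohort": cohort,
        "ground_truth": truth,
        "prepared": prepared,
        "models": models,
        "errors": errors,
        "report": report,
    }
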