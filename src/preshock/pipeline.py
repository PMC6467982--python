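"""End-to-end study driver: simulate -> label -> train -> evaluate.

Ties the stages together the way the analysis is meant to run: generate (or
accept) a cohort, label it under Sepsis-3, build the truncated feature
matrix, split patients 70/30 into training and testing sets, normalize on
training patients only, train the chosen risk model on pre-shock-window vs
non-shock sepsis samples, and evaluate threshold-crossing detection on the
held-out patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detection import EvaluationReport, evaluate_trajectories, risk_trajectories
from .features import (
    FIG_FEATURES,
    build_feature_matrix,
    extract_training_samples,
    fit_apply_normalizer,
)
from .labeling import sepsis3_labels
from .models import PreShockGLM, XGBoostRiskModel, build_cox_inputs, CoxRiskModel
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    report: EvaluationReport
    model: object
    normalizer: object
    train_ids: list[str]
    test_ids: list[str]
    matrix: object
    trajectories: list


def run_study(
    config: CohortConfig | None = None,
    seed: int = 0,
    model: str = "glm",
    window_end_offset: float = -1.0,
    test_fraction: float = 0.3,
    threshold: float | str = "auto",
    timelines=None,
    label_sequences=None,
) -> StudyResult:
    """Run the full pipeline on a synthetic (or provided) cohort.

    ``seed`` drives the train/test split and the model's internal
    randomness; the cohort itself is reproducible through ``config.seed``.
    """
    if timelines is None:
        config = config or CohortConfig(seed=seed)
        timelines, _truth = generate_cohort(config)
    if label_sequences is None:
        label_sequences = {pid: sepsis3_labels(tl) for pid, tl in timelines.items()}

    matrix = build_feature_matrix(timelines, label_sequences, feature_set=FIG_FEATURES)
    pids = list(dict.fromkeys(matrix.patient_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pids))
    n_test = int(round(test_fraction * len(pids)))
    test_ids = [pids[i] for i in perm[:n_test]]
    train_ids = [pids[i] for i in perm[n_test:]]

    normalizer, _ = fit_apply_normalizer(matrix, train_ids)
    train_matrix = matrix.rows_for(train_ids)
    training = extract_training_samples(train_matrix, window_end_offset=window_end_offset)
    Xtr = normalizer.transform(training.X)

    if model == "glm":
        fitted = PreShockGLM(random_state=seed).fit(Xtr, training.y, groups=training.groups)
    elif model == "xgboost":
        fitted = XGBoostRiskModel(random_state=seed).fit(Xtr, training.y)
    elif model == "cox":
        obs_end = {pid: tl.observation_end for pid, tl in timelines.items()}
        Ztr = normalizer.transform(train_matrix.X)
        Zc, dur, ev, grp = build_cox_inputs(train_matrix, Ztr, obs_end)
        fitted = CoxRiskModel(random_state=seed).fit(Zc, dur, ev, groups=grp)
    else:
        raise ValueError(f"unknown model kind {model!r}")

    test_matrix = matrix.rows_for(test_ids)
    trajectories = risk_trajectories(fitted, normalizer, test_matrix)
    report = evaluate_trajectories(trajectories, threshold=threshold)
    return StudyResult(
        report=report,
        model=fitted,
        normalizer=normalizer,
        train_ids=train_ids,
        test_ids=test_ids,
        matrix=matrix,
        trajectories=trajectories,
    )
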