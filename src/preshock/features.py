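"""Per-timestamp feature matrices and pre-shock training-set construction.

The risk models consume one row per unique observation timestamp per
patient: raw physiological features are carried forward, SOFA-subscore
features are computed from trailing 24 h worst values, and rows of shock
patients are truncated at shock onset (the evaluation never sees post-onset
data). Normalization is z-scoring with means/SDs estimated on training
patients only (sample SD, ddof=1); missing entries become 0 after
normalization, i.e. mean imputation on the original scale, which keeps a
linear model's contribution for an unseen feature neutral.

The positive class for training is drawn from an hour-long window anchored
to shock onset: with the default window end offset of -1 h the window is
[t_o - 2, t_o - 1], the configuration found to detect best; the window end
offset can be swept from -11 h to +4 h to probe how far ahead of onset the
pre-shock signature is present. The negative class is every sepsis-labeled
row of patients who never entered shock.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ehr import PatientTimeline
from .labeling import (
    SEPSIS,
    SEPSIS_AGGREGATE,
    ClinicalStateSequence,
    sofa_scores,
)

logger = logging.getLogger(__name__)

#: the ten model features found most useful for detection
FIG_FEATURES = (
    "lactate",
    "cardiovascular_sofa",
    "gcs",
    "heart_rate",
    "pao2",
    "fio2",
    "bun",
    "respiratory_rate",
    "respiratory_sofa",
    "coagulation_sofa",
)

_SOFA_FEATURES = {
    "respiratory_sofa": "respiration",
    "coagulation_sofa": "coagulation",
    "liver_sofa": "liver",
    "cardiovascular_sofa": "cardiovascular",
    "cns_sofa": "cns",
    "renal_sofa": "renal",
    "sofa_total": "total",
}

_SEPSIS_STATES = (SEPSIS, SEPSIS_AGGREGATE)


@dataclass
class FeatureMatrix:
    """Carried-forward feature rows at unique (patient, time) pairs.

    ``data`` holds patient_id/time plus one column per feature (NaN where no
    prior observation exists -- ``mask`` is True there); ``states`` is the
    clinical-state label active at each row; ``shock_onset`` maps shock
    patients to their onset time ``t_o``.
    """

    data: pd.DataFrame
    mask: pd.DataFrame
    states: np.ndarray
    feature_names: tuple[str, ...]
    shock_onset: dict[str, float]

    @property
    def X(self) -> pd.DataFrame:
        return self.data[list(self.feature_names)]

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data["patient_id"].to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def rows_for(self, patient_ids: Iterable[str]) -> "FeatureMatrix":
        keep = self.data["patient_id"].isin(set(patient_ids)).to_numpy()
        return FeatureMatrix(
            data=self.data.loc[keep].reset_index(drop=True),
            mask=self.mask.loc[keep].reset_index(drop=True),
            states=self.states[keep],
            feature_names=self.feature_names,
            shock_onset={
                p: t for p, t in self.shock_onset.items() if p in set(patient_ids)
            },
        )


@dataclass
class TrainingSet:
    """Labeled feature vectors: pre-shock-window rows (1) vs non-shock sepsis rows (0)."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray  # patient id per row, for patient-wise CV folds
    window_end_offset: float
    window_length: float

    @property
    def window(self) -> tuple[float, float]:
        """Window [t_o + end_offset - length, t_o + end_offset] relative to onset."""
        return (self.window_end_offset - self.window_length, self.window_end_offset)


def build_feature_matrix(
    timelines: Mapping[str, PatientTimeline],
    label_sequences: Mapping[str, ClinicalStateSequence],
    feature_set: Sequence[str] = FIG_FEATURES,
    truncate_at_onset: bool = True,
    sofa_window: float = 24.0,
) -> FeatureMatrix:
    """One row per unique observation timestamp per patient.

    Raw features are carried forward; ``*_sofa`` columns are computed from
    the trailing-window worst values. With ``truncate_at_onset`` (the
    default) a shock patient contributes rows strictly before ``t_o`` only.
    """
    feature_set = tuple(feature_set)
    raw = [f for f in feature_set if f not in _SOFA_FEATURES]
    derived = [f for f in feature_set if f in _SOFA_FEATURES]
    for tl in timelines.values():
        for f in raw:
            tl._check_feature(f)
        break

    frames, masks, states_all = [], [], []
    shock_onset: dict[str, float] = {}
    for pid, tl in timelines.items():
        seq = label_sequences[pid]
        times = tl.unique_event_times()
        if seq.shock_onset is not None:
            shock_onset[pid] = seq.shock_onset
            if truncate_at_onset:
                times = times[times < seq.shock_onset]
        if len(times) == 0:
            continue
        cols: dict[str, np.ndarray] = {}
        for f in raw:
            cols[f] = tl.values_at(f, times)
        if derived:
            sofa = sofa_scores(tl, times, window=sofa_window)
            for f in derived:
                cols[f] = sofa[_SOFA_FEATURES[f]].astype(float)
        df = pd.DataFrame(cols, columns=list(feature_set))
        df.insert(0, "time", times)
        df.insert(0, "patient_id", pid)
        frames.append(df)
        masks.append(df[list(feature_set)].isna())
        states_all.append(np.asarray(seq.state_at(times), dtype=object))

    if not frames:
        raise ValueError("no rows: every timeline was empty or truncated away")
    data = pd.concat(frames, ignore_index=True)
    mask = pd.concat(masks, ignore_index=True)
    return FeatureMatrix(
        data=data,
        mask=mask,
        states=np.concatenate(states_all),
        feature_names=feature_set,
        shock_onset=shock_onset,
    )


class RiskFeatureNormalizer(TransformerMixin, BaseEstimator):
    """Z-score normalizer fit on training rows only (sample SD, ddof=1).

    Zero-variance features are dropped with a warning; missing entries map
    to 0 after normalization (the training mean). Accepts and returns
    pandas DataFrames, preserving the kept-column order.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        means = X.mean(axis=0, skipna=True)
        sds = X.std(axis=0, ddof=1, skipna=True)
        degenerate = [c for c in X.columns if not np.isfinite(sds[c]) or sds[c] <= 0]
        if degenerate:
            warnings.warn(
                f"dropping zero-variance feature(s): {', '.join(map(str, degenerate))}",
                UserWarning,
                stacklevel=2,
            )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.kept_features_ = [c for c in X.columns if c not in degenerate]
        self.dropped_features_ = degenerate
        self.means_ = means[self.kept_features_].to_numpy(dtype=float)
        self.scales_ = sds[self.kept_features_].to_numpy(dtype=float)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        X = pd.DataFrame(X)
        Z = (X[self.kept_features_] - self.means_) / self.scales_
        return Z.fillna(0.0)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "means_")
        return np.asarray(self.kept_features_, dtype=object)


def fit_apply_normalizer(
    matrix: FeatureMatrix, training_patient_ids: Iterable[str]
) -> tuple[RiskFeatureNormalizer, pd.DataFrame]:
    """Fit the z-score normalizer on the training patients' rows, apply to all rows."""
    training_patient_ids = set(training_patient_ids)
    if not training_patient_ids:
        raise ValueError("training_patient_ids must be non-empty")
    train_rows = matrix.data["patient_id"].isin(training_patient_ids).to_numpy()
    norm = RiskFeatureNormalizer().fit(matrix.X.loc[train_rows])
    return norm, norm.transform(matrix.X)


def extract_training_samples(
    matrix: FeatureMatrix,
    window_end_offset: float = -1.0,
    window_length: float = 1.0,
) -> TrainingSet:
    """Build the labeled training set from a feature matrix.

    Label 1: rows of shock patients with time in the closed interval
    ``[t_o + window_end_offset - window_length, t_o + window_end_offset]``.
    Label 0: every sepsis-labeled row of patients who never entered shock.
    Positive-offset windows reach past onset and therefore require a matrix
    built with ``truncate_at_onset=False``.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    pids = matrix.patient_ids
    times = matrix.times
    is_shock_patient = np.isin(pids, list(matrix.shock_onset))

    onset = np.full(len(pids), np.nan)
    for p, t_o in matrix.shock_onset.items():
        onset[pids == p] = t_o
    rel = times - onset
    with np.errstate(invalid="ignore"):
        pos_mask = is_shock_patient & (rel >= window_end_offset - window_length) & (
            rel <= window_end_offset
        )
    neg_mask = ~is_shock_patient & np.isin(matrix.states, _SEPSIS_STATES)

    if not pos_mask.any():
        raise ValueError(
            "empty positive class: no shock patient has rows inside the window "
            f"ending at t_o{window_end_offset:+g}h"
        )

    # leakage guards, asserted on every build
    assert not np.any(pos_mask & ~is_shock_patient), "label-1 row from a non-shock patient"
    assert not np.any(neg_mask & is_shock_patient), "label-0 row from a shock patient"
    assert np.all(rel[pos_mask] <= window_end_offset + 1e-9), "label-1 row beyond window end"

    keep = pos_mask | neg_mask
    X = matrix.X.loc[keep].reset_index(drop=True)
    y = pos_mask[keep].astype(int)
    return TrainingSet(
        X=X,
        y=y,
        groups=pids[keep],
        window_end_offset=float(window_end_offset),
        window_length=float(window_length),
    )


def sweep_training_windows(
    matrix: FeatureMatrix,
    end_offsets: Sequence[float] = tuple(range(-11, 5)),
    window_length: float = 1.0,
) -> dict[float, TrainingSet]:
    """Candidate training sets over a sweep of window end offsets.

    The default sweep covers hour-long windows beginning 12 h before onset
    through 3 h after (end offsets -11 .. +4). Offsets > 0 need an
    untruncated matrix.
    """
    out = {}
    for off in end_offsets:
        try:
            out[float(off)] = extract_training_samples(
                matrix, window_end_offset=off, window_length=window_length
            )
        except ValueError as exc:
            logger.warning("window end offset %+g h skipped: %s", off, exc)
    return out
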