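"""Synthetic EHR cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without access to a credentialed clinical database:

* irregular per-feature observation times (independent Poisson processes,
  with labs charted more sparsely than vitals);
* a non-sepsis -> sepsis -> (pre-shock -> septic shock) state progression per
  patient, with state-conditional physiology drawn from configurable
  mean/SD tables (sepsis, pre-shock and shock defaults follow the published
  state-contrast values for lactate, GCS, heart rate, PaO2 and FiO2);
* treatment events arranged so that a shock patient satisfies every Sepsis-3
  septic-shock condition for the first time exactly at the ground-truth
  onset ``t_o``: antibiotic and culture orders early in the record, fluid
  boluses reaching 30 mL/kg shortly before onset, a vasopressor start at
  onset, and lactate/MAP measurements at onset consistent with shock.

Within a state, draws are i.i.d. truncated normals; truncation is wide
(mean +/- 8 SD) so configured moments are preserved, and emitted measurement
values are then clipped into plausibility bounds (a charted lactate cannot
be negative). GCS is rounded and clipped to the 3-15 scale.

A separate direct sampler (:func:`simulate_training_samples`) draws labeled
feature vectors from an explicit logistic risk link in z-scored features
(default odds ratio 5 per SD for lactate, the remaining effects ordered by
decreasing importance), for parameter-recovery experiments on the modeling
stage in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ehr import EventRecord, FeatureDictionary, PatientTimeline, TreatmentEvent

#: state-conditional physiology: feature -> state -> (mean, sd).
#: sepsis/pre_shock/shock rows for lactate, gcs, heart_rate, pao2 and fio2
#: follow the published sepsis -> pre-shock -> septic-shock contrast; the
#: remaining features (and the non_sepsis column) are the generator's own
#: clinically plausible defaults.
DEFAULT_STATE_PHYSIOLOGY: dict[str, dict[str, tuple[float, float]]] = {
    "lactate": {
        "non_sepsis": (1.0, 0.5),
        "sepsis": (3.15, 2.71),
        "pre_shock": (4.57, 3.69),
        "shock": (4.98, 3.67),
    },
    "gcs": {
        "non_sepsis": (14.6, 0.8),
        "sepsis": (9.72, 4.26),
        "pre_shock": (8.22, 4.01),
        "shock": (7.72, 3.80),
    },
    "heart_rate": {
        "non_sepsis": (80.0, 10.0),
        "sepsis": (97.7, 22.2),
        "pre_shock": (97.3, 22.4),
        "shock": (96.2, 20.3),
    },
    "pao2": {
        "non_sepsis": (95.0, 15.0),
        "sepsis": (127.4, 71.1),
        "pre_shock": (132.4, 78.2),
        "shock": (119.1, 68.7),
    },
    "fio2": {
        "non_sepsis": (0.21, 0.02),
        "sepsis": (0.62, 0.24),
        "pre_shock": (0.61, 0.22),
        "shock": (0.59, 0.20),
    },
    "map": {
        "non_sepsis": (85.0, 9.0),
        "sepsis": (80.0, 10.0),
        "pre_shock": (61.0, 6.0),
        "shock": (60.0, 6.0),
    },
    "respiratory_rate": {
        "non_sepsis": (16.0, 3.0),
        "sepsis": (20.0, 5.5),
        "pre_shock": (26.0, 6.0),
        "shock": (27.0, 6.0),
    },
    "temperature": {
        "non_sepsis": (36.8, 0.4),
        "sepsis": (37.6, 1.1),
        "pre_shock": (37.7, 1.1),
        "shock": (37.4, 1.2),
    },
    "wbc": {
        "non_sepsis": (8.0, 2.0),
        "sepsis": (13.0, 6.0),
        "pre_shock": (15.5, 6.5),
        "shock": (16.0, 7.0),
    },
    "platelets": {
        "non_sepsis": (250.0, 60.0),
        "sepsis": (190.0, 80.0),
        "pre_shock": (120.0, 70.0),
        "shock": (110.0, 70.0),
    },
    "bilirubin": {
        "non_sepsis": (0.7, 0.3),
        "sepsis": (1.4, 1.4),
        "pre_shock": (2.4, 2.0),
        "shock": (2.6, 2.2),
    },
    "creatinine": {
        "non_sepsis": (0.9, 0.3),
        "sepsis": (1.5, 1.1),
        "pre_shock": (2.4, 1.3),
        "shock": (2.6, 1.4),
    },
    "bun": {
        "non_sepsis": (15.0, 5.0),
        "sepsis": (28.0, 16.0),
        "pre_shock": (44.0, 18.0),
        "shock": (46.0, 18.0),
    },
    "paco2": {
        "non_sepsis": (40.0, 4.0),
        "sepsis": (35.0, 6.0),
        "pre_shock": (34.0, 6.0),
        "shock": (33.0, 6.0),
    },
}

#: vitals are charted more often than labs; everything else counts as a lab.
VITAL_FEATURES = ("heart_rate", "map", "respiratory_rate", "temperature", "gcs", "fio2")

#: exponentiated logistic coefficients (odds ratios per SD) of the risk link
#: used by the direct training-sample simulator, ordered by decreasing
#: |log odds ratio|; lactate's value of 5 is the headline effect size.
DEFAULT_RISK_LINK: dict[str, float] = {
    "lactate": 5.0,
    "cardiovascular_sofa": 2.5,
    "gcs": 0.5,
    "heart_rate": 1.8,
    "pao2": 1.55,
    "fio2": 1.45,
    "bun": 1.35,
    "respiratory_rate": 1.3,
    "respiratory_sofa": 1.25,
    "coagulation_sofa": 1.2,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the package's study conditions."""

    n_patients: int = 200
    shock_fraction: float = 0.3
    sampling_rate_per_feature: float = 0.5  # events/hour for vitals
    lab_sparsity: float = 4.0  # labs sampled at rate / lab_sparsity
    state_physiology: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_STATE_PHYSIOLOGY
    )
    pre_shock_duration: float = 2.0  # hours spent in the pre-shock state
    deterioration_hours: float = 12.0  # gradual sepsis -> pre-shock drift before onset
    deterioration_shape: float = 1.0  # ramp exponent; >1 concentrates the drift near onset
    between_patient_sd_fraction: float = 0.8  # share of state SD that is a stable patient offset
    risk_link: Mapping[str, float] = field(default_factory=lambda: DEFAULT_RISK_LINK)
    truncation_sds: float = 8.0  # truncated-normal half-width in SD units
    sepsis_onset_range: tuple[float, float] = (4.0, 12.0)
    shock_onset_range: tuple[float, float] = (24.0, 72.0)
    non_shock_duration_range: tuple[float, float] = (48.0, 96.0)
    post_onset_hours: float = 6.0
    fluid_ml_per_kg: float = 40.0  # planted resuscitation volume (rule needs 30)
    ar1_rho: float = 0.0  # optional within-state AR(1) smoothing, off by default
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shock_fraction <= 1.0):
            raise ValueError("shock_fraction must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.sampling_rate_per_feature <= 0:
            raise ValueError("sampling_rate_per_feature must be > 0")
        for feat, states in self.state_physiology.items():
            for state, (_, sd) in states.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {feat}/{state}")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        if not (0.0 <= self.between_patient_sd_fraction < 1.0):
            raise ValueError("between_patient_sd_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """True per-patient progression times recorded by the generator."""

    patient_id: list[str] = field(default_factory=list)
    is_shock: list[bool] = field(default_factory=list)
    sepsis_onset: list[float] = field(default_factory=list)
    pre_shock_entry: list[float] = field(default_factory=list)  # NaN for non-shock
    shock_onset: list[float] = field(default_factory=list)  # NaN for non-shock

    def add(self, pid, is_shock, sepsis_onset, pre_shock_entry, shock_onset):
        self.patient_id.append(pid)
        self.is_shock.append(bool(is_shock))
        self.sepsis_onset.append(float(sepsis_onset))
        self.pre_shock_entry.append(float(pre_shock_entry))
        self.shock_onset.append(float(shock_onset))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "is_shock": self.is_shock,
                "sepsis_onset": self.sepsis_onset,
                "pre_shock_entry": self.pre_shock_entry,
                "shock_onset": self.shock_onset,
            }
        )

    def onset_of(self, pid: str) -> float | None:
        i = self.patient_id.index(pid)
        t = self.shock_onset[i]
        return None if np.isnan(t) else t


def _draw_feature(
    config: CohortConfig, feature: str, state: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    states = config.state_physiology.get(feature)
    if states is None or state not in states:
        raise KeyError(f"no physiology configured for feature {feature!r}, state {state!r}")
    mean, sd = states[state]
    if sd == 0 or n == 0:
        return np.full(n, float(mean))
    w = config.truncation_sds
    draws = stats.truncnorm.rvs(-w, w, loc=mean, scale=sd, size=n, random_state=rng)
    if config.ar1_rho > 0 and n > 1:
        rho = config.ar1_rho
        z = (draws - mean) / sd
        sm = np.empty_like(z)
        sm[0] = z[0]
        for i in range(1, n):
            sm[i] = rho * sm[i - 1] + np.sqrt(1 - rho**2) * z[i]
        draws = mean + sd * sm
    return draws


def sample_state_vector(
    config: CohortConfig, state: str, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` state-conditional feature vectors (one column per feature).

    Draws are truncated normals at ``truncation_sds`` half-width, so sample
    moments converge to the configured means/SDs; measurement-scale
    postprocessing (clipping, GCS rounding) is applied only when values are
    emitted into timelines, not here.
    """
    known_states = {s for states in config.state_physiology.values() for s in states}
    if state not in known_states:
        raise KeyError(f"unknown state {state!r}; configured states: {sorted(known_states)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return pd.DataFrame(
        {
            feat: _draw_feature(config, feat, state, n, rng)
            for feat in config.state_physiology
        }
    )


def _postprocess(feature: str, values: np.ndarray, dictionary: FeatureDictionary) -> np.ndarray:
    lo, hi = dictionary.bounds_for_feature(feature)
    values = np.clip(values, lo, hi)
    if feature == "gcs":
        values = np.clip(np.rint(values), 3, 15)
    return values


def _state_params(
    config: CohortConfig, feature: str, times: np.ndarray, t_sep: float, t_o: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time (mean, sd) for one feature along a patient's progression.

    Patients hold the non-sepsis values before ``t_sep`` and the sepsis
    values after. Shock patients drift linearly from the sepsis toward the
    pre-shock values over the ``deterioration_hours`` before pre-shock
    entry (physiology worsens gradually, which is the premise that makes
    early prediction possible at all), hold the pre-shock values for
    ``pre_shock_duration``, and switch to the shock values at ``t_o``.
    """
    states = config.state_physiology[feature]
    mean = np.full(len(times), states["non_sepsis"][0])
    sd = np.full(len(times), states["non_sepsis"][1])
    sep = times >= t_sep
    mean[sep], sd[sep] = states["sepsis"]
    if t_o is not None:
        pre_entry = t_o - config.pre_shock_duration
        ramp_start = max(t_sep, pre_entry - config.deterioration_hours)
        if pre_entry > ramp_start:
            in_ramp = (times >= ramp_start) & (times < pre_entry)
            w = (times[in_ramp] - ramp_start) / (pre_entry - ramp_start)
            w = w ** config.deterioration_shape
            mean[in_ramp] = (1 - w) * states["sepsis"][0] + w * states["pre_shock"][0]
            sd[in_ramp] = (1 - w) * states["sepsis"][1] + w * states["pre_shock"][1]
        pre = times >= pre_entry
        mean[pre], sd[pre] = states["pre_shock"]
        shock = times >= t_o
        mean[shock], sd[shock] = states["shock"]
    return mean, sd


def generate_cohort(config: CohortConfig) -> tuple[dict[str, PatientTimeline], GroundTruth]:
    """Generate a cohort of timelines plus ground-truth progression times.

    Every patient has early concomitant antibiotic/culture orders (suspected
    infection precedes sepsis onset). Shock patients additionally receive two
    fluid boluses totalling ``fluid_ml_per_kg`` in the three hours before
    onset, a vasopressor start at ``t_o``, and planted lactate (> 2 mmol/L)
    and MAP measurements at ``t_o``, plus a lactate/MAP draw inside the
    pre-shock window (deterioration triggers a lab draw, as it does
    clinically) -- so the Sepsis-3 labeler can recover ``t_o`` from the
    record alone.
    """
    dictionary = FeatureDictionary.default()
    root = np.random.SeedSequence(config.seed)
    child_seeds = root.spawn(config.n_patients + 1)
    head_rng = np.random.default_rng(child_seeds[0])
    is_shock_flags = head_rng.random(config.n_patients) < config.shock_fraction

    timelines: dict[str, PatientTimeline] = {}
    truth = GroundTruth()
    features = list(config.state_physiology)
    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        rng = np.random.default_rng(child_seeds[i + 1])
        weight = float(np.clip(rng.normal(80.0, 15.0), 40.0, 160.0))
        is_shock = bool(is_shock_flags[i])
        t_sep = rng.uniform(*config.sepsis_onset_range)
        if is_shock:
            t_o = rng.uniform(*config.shock_onset_range)
            pre_entry = t_o - config.pre_shock_duration
            obs_end = t_o + config.post_onset_hours
        else:
            t_o = pre_entry = None
            obs_end = rng.uniform(*config.non_shock_duration_range)

        events: list[EventRecord] = []
        for feat in features:
            rate = config.sampling_rate_per_feature
            if feat not in VITAL_FEATURES:
                rate /= config.lab_sparsity
            n_obs = rng.poisson(rate * obs_end)
            times = np.sort(rng.uniform(0.0, obs_end, size=n_obs))
            mean_t, sd_t = _state_params(config, feat, times, t_sep, t_o)
            # split the state SD into a stable per-patient offset plus
            # within-patient measurement noise; the marginal across patients
            # keeps the configured mean and SD
            f = config.between_patient_sd_fraction
            g = np.sqrt(1.0 - f**2)
            u = rng.standard_normal()  # patient-level offset, z units
            w = config.truncation_sds
            zdraw = stats.truncnorm.rvs(-w, w, size=n_obs, random_state=rng)
            if config.ar1_rho > 0 and n_obs > 1:
                rho = config.ar1_rho
                for k in range(1, n_obs):
                    zdraw[k] = rho * zdraw[k - 1] + np.sqrt(1 - rho**2) * zdraw[k]
            values = _postprocess(feat, mean_t + sd_t * (f * u + g * zdraw), dictionary)
            events.extend(EventRecord(pid, float(t), feat, float(v)) for t, v in zip(times, values))

        treatments: list[TreatmentEvent] = []
        t_abx = rng.uniform(0.0, min(1.5, t_sep))
        t_cul = t_abx + rng.uniform(0.0, 3.0)
        treatments.append(TreatmentEvent(pid, t_abx, "antibiotic_order", agent="antibiotic"))
        treatments.append(TreatmentEvent(pid, t_cul, "culture_order"))

        if is_shock:
            half = config.fluid_ml_per_kg * weight / 2.0
            treatments.append(TreatmentEvent(pid, t_o - 3.0, "fluid_bolus", dose=half))
            treatments.append(TreatmentEvent(pid, t_o - 1.5, "fluid_bolus", dose=half))
            dose = float(rng.uniform(0.05, 0.3))
            treatments.append(
                TreatmentEvent(pid, t_o, "vasopressor", dose=dose, agent="norepinephrine")
            )
            # planted measurements: pre-shock window draw + onset values that
            # satisfy the shock criteria (lactate > 2, MAP consistent with a
            # vasopressor-maintained target)
            lac_pre = _postprocess(
                "lactate", _draw_feature(config, "lactate", "pre_shock", 1, rng), dictionary
            )[0]
            map_pre = _postprocess(
                "map", _draw_feature(config, "map", "pre_shock", 1, rng), dictionary
            )[0]
            events.append(EventRecord(pid, t_o - 1.8, "map", float(map_pre)))
            events.append(EventRecord(pid, t_o - 1.5, "lactate", float(lac_pre)))
            mean, sd = config.state_physiology["lactate"]["shock"]
            a = (2.0 + 1e-6 - mean) / sd
            lac_onset = stats.truncnorm.rvs(a, config.truncation_sds, loc=mean, scale=sd, random_state=rng)
            events.append(EventRecord(pid, t_o, "lactate", float(lac_onset)))
            events.append(EventRecord(pid, t_o, "map", float(rng.uniform(58.0, 66.0))))
        else:
            if rng.random() < 0.3:  # occasional small maintenance bolus
                treatments.append(
                    TreatmentEvent(
                        pid, rng.uniform(0.0, obs_end), "fluid_bolus", dose=float(rng.uniform(250, 750))
                    )
                )

        timelines[pid] = PatientTimeline(
            pid,
            events,
            treatments,
            weight_kg=weight,
            observation_end=obs_end,
            known_features=dictionary.canonical_features,
        )
        truth.add(
            pid,
            is_shock,
            t_sep,
            pre_entry if pre_entry is not None else np.nan,
            t_o if t_o is not None else np.nan,
        )
    return timelines, truth


def simulate_training_samples(
    n: int,
    seed: int,
    risk_link: Mapping[str, float] | None = None,
    intercept: float = -1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw labeled feature vectors directly from the logistic risk link.

    Features are i.i.d. standard normal (already on the z-score scale);
    membership in the pre-shock window follows
    ``P(y=1 | x) = logistic(intercept + sum_j log(OR_j) * x_j)`` with the
    configured odds ratios. Returns ``(X, y)``.
    """
    link = dict(risk_link or DEFAULT_RISK_LINK)
    rng = np.random.default_rng(seed)
    names = list(link)
    X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    beta = np.log(np.asarray([link[f] for f in names], dtype=float))
    logits = intercept + X.to_numpy() @ beta
    p = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(n) < p).astype(int)
    return X, y
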