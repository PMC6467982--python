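"""Shared fixtures: hand-built toy timelines and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import preshock as ps

FEATURES = (
    "lactate",
    "map",
    "gcs",
    "heart_rate",
    "pao2",
    "fio2",
    "platelets",
    "bilirubin",
    "creatinine",
    "respiratory_rate",
    "temperature",
    "wbc",
    "paco2",
    "bun",
)


def make_timeline(events=(), treatments=(), weight=80.0, pid="toy", obs_end=None):
    """Build a timeline from (time, feature, value) and (time, kind, dose, agent) tuples."""
    evs = [ps.EventRecord(pid, t, f, v) for (t, f, v) in events]
    trs = [
        ps.TreatmentEvent(pid, t, k, dose=d, agent=a) for (t, k, d, a) in treatments
    ]
    return ps.PatientTimeline(pid, evs, trs, weight_kg=weight, observation_end=obs_end)


def random_timeline(rng: np.random.Generator, pid="rnd", max_events=12, horizon=48.0):
    """A small random timeline over a subset of features, with random treatments."""
    events = []
    for feat in rng.choice(FEATURES, size=rng.integers(2, 6), replace=False):
        n = rng.integers(1, max_events)
        times = rng.uniform(0, horizon, size=n)
        lo, hi = ps.FeatureDictionary.default().bounds_for_feature(feat)
        lo = max(lo, -50.0)
        hi = min(hi, 500.0)
        for t in times:
            events.append((float(t), feat, float(rng.uniform(lo, hi))))
    treatments = []
    if rng.random() < 0.5:
        treatments.append((float(rng.uniform(0, horizon)), "antibiotic_order", None, None))
        treatments.append((float(rng.uniform(0, horizon)), "culture_order", None, None))
    if rng.random() < 0.4:
        agent = str(rng.choice(["norepinephrine", "dopamine", "dobutamine"]))
        treatments.append(
            (float(rng.uniform(0, horizon)), "vasopressor", float(rng.uniform(0, 0.4)), agent)
        )
    if rng.random() < 0.4:
        treatments.append(
            (float(rng.uniform(0, horizon)), "fluid_bolus", float(rng.uniform(100, 3000)), None)
        )
    return make_timeline(events, treatments, pid=pid, obs_end=horizon)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient default-configuration synthetic cohort with ground truth."""
    config = ps.CohortConfig(n_patients=150, seed=42)
    timelines, truth = ps.generate_cohort(config)
    return config, timelines, truth


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    _, timelines, _ = small_cohort
    return {pid: ps.sepsis3_labels(tl) for pid, tl in timelines.items()}
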