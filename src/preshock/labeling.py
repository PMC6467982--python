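"""Temporal clinical-state labeling under Sepsis-3 and Sepsis-2 criteria.

At every unique event or treatment timestamp a patient is assigned one of
``non_sepsis`` / ``sepsis`` / ``septic_shock`` (Sepsis-3) or ``non_sepsis`` /
``sepsis_severe_sepsis`` / ``septic_shock`` (Sepsis-2, with sepsis and severe
sepsis aggregated). Shock onset time ``t_o`` is the earliest timestamp at
which every condition of septic shock holds simultaneously.

The two criteria families deliberately differ in how they read the record:

* SOFA subscores use the *worst* observed value over the preceding 24 h, so
  Sepsis-3 labels are temporally smooth;
* SIRS criteria use the *current* carried-forward values, so Sepsis-2 labels
  flip whenever a vital sign wanders across a threshold.

This asymmetry is preserved on purpose: it is what makes Sepsis-2 labels
temporally unstable relative to Sepsis-3, and quantifying that instability
(dwell times, label changes) is one of the jobs of this module.

Operational choices the consensus definitions leave open (and the package
pins, configurably): "adequate fluid resuscitation" defaults to a cumulative
bolus volume of at least 30 mL/kg over the trailing 24 h; "requires
vasopressors to maintain MAP >= 65" is operationalized as an active
vasopressor at a dose > 0 (carried forward until an explicit stop) -- no
counterfactual blood-pressure reasoning is attempted, since onset must be
computable from the record alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ehr import PatientTimeline, _load_fixture

logger = logging.getLogger(__name__)

NON_SEPSIS = "non_sepsis"
SEPSIS = "sepsis"
SEPSIS_AGGREGATE = "sepsis_severe_sepsis"
SEPTIC_SHOCK = "septic_shock"

SOFA_SYSTEMS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")


def sofa_table() -> dict:
    """The shipped SOFA threshold fixture (parsed)."""
    return _load_fixture("sofa_thresholds.yaml")


def sirs_table() -> dict:
    """The shipped SIRS criteria fixture (parsed)."""
    return _load_fixture("sirs_criteria.yaml")


_SOFA = sofa_table()
_SIRS = sirs_table()


@dataclass(frozen=True)
class SofaScore:
    time: float
    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int

    @property
    def total(self) -> int:
        return (
            self.respiration
            + self.coagulation
            + self.liver
            + self.cardiovascular
            + self.cns
            + self.renal
        )

    def __post_init__(self):
        for name in SOFA_SYSTEMS:
            v = getattr(self, name)
            if not (0 <= v <= 4):
                raise ValueError(f"SOFA subscore {name}={v} outside 0..4")


@dataclass(frozen=True)
class FluidRule:
    """Adequate-resuscitation rule: >= ``ml_per_kg`` of boluses within ``window`` hours."""

    ml_per_kg: float = 30.0
    window: float = 24.0


@dataclass(frozen=True)
class InfectionParams:
    window: float = 24.0            # concomitant dialect: |t_abx - t_culture| <= window
    abx_first_window: float = 24.0  # seymour dialect: culture within this many hours after abx
    culture_first_window: float = 72.0  # seymour dialect: abx within this many hours after culture


@dataclass
class ClinicalStateSequence:
    """Per-timestamp clinical-state labels for one patient."""

    patient_id: str
    times: np.ndarray
    labels: np.ndarray  # array of state strings, one per timestamp
    criteria: str  # 'sepsis3' | 'sepsis2'
    suspected_infection_time: float | None
    shock_onset: float | None
    observation_end: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def state_at(self, t) -> np.ndarray | str:
        """State label carried forward to time(s) ``t`` (non_sepsis before the first stamp)."""
        scalar = np.isscalar(t)
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, tq, side="right") - 1
        out = np.where(idx >= 0, self.labels[np.clip(idx, 0, None)], NON_SEPSIS)
        return out[0] if scalar else out


@dataclass
class StabilityStats:
    """Dwell-time and label-change summaries over a set of label sequences."""

    dwell_times: dict[str, np.ndarray]
    mean_dwell: dict[str, float]
    median_dwell: dict[str, float]
    label_changes: np.ndarray  # one count per patient
    mean_changes: float
    median_changes: float


# -- suspected infection ----------------------------------------------------


def suspected_infection_times(
    timeline: PatientTimeline,
    dialect: str = "concomitant",
    params: InfectionParams | None = None,
) -> float | None:
    """Earliest suspected-infection time under the chosen dialect, or None.

    ``concomitant``: an antibiotic and a culture order within ``params.window``
    of one another, in either order. ``seymour``: antibiotic first with the
    culture within ``abx_first_window``, or culture first with the antibiotic
    within ``culture_first_window``. In both dialects the reported time is the
    earlier of the two orders in the qualifying pair.
    """
    if dialect not in ("concomitant", "seymour"):
        raise ValueError(f"unknown infection dialect {dialect!r}")
    params = params or InfectionParams()
    abx, _, _ = timeline.treatment_times("antibiotic_order")
    cul, _, _ = timeline.treatment_times("culture_order")
    if len(abx) == 0 or len(cul) == 0:
        return None
    a = abx[:, None]
    c = cul[None, :]
    if dialect == "concomitant":
        ok = np.abs(a - c) <= params.window
    elif dialect == "seymour":
        ok = ((c >= a) & (c - a <= params.abx_first_window)) | (
            (a >= c) & (a - c <= params.culture_first_window)
        )
    else:
        raise ValueError(f"unknown infection dialect {dialect!r}")
    if not ok.any():
        return None
    return float(np.minimum(a, c)[ok].min())


# -- SOFA -------------------------------------------------------------------


def _band_scores(worst: np.ndarray, thresholds, direction: str) -> np.ndarray:
    """Score 0-4 from worst values against a 4-step threshold ladder (NaN -> 0)."""
    worst = np.asarray(worst, dtype=float)
    scores = np.zeros(len(worst), dtype=int)
    ok = ~np.isnan(worst)
    for i, thr in enumerate(thresholds, start=1):
        if direction == "lt":
            scores[ok & (worst < thr)] = i
        else:
            scores[ok & (worst >= thr)] = i
    return scores


def _cardiovascular_scores(
    timeline: PatientTimeline, times: np.ndarray, window: float
) -> np.ndarray:
    cfg = _SOFA["cardiovascular"]
    map_worst = timeline.extrema_in_window("map", times, window, "min")
    scores = np.where(~np.isnan(map_worst) & (map_worst < cfg["map_threshold"]), 1, 0)
    agents = cfg["agents"]
    for start, end, dose, agent in timeline.vasopressor_intervals():
        spec = agents.get(agent, agents[cfg["default_agent"]])
        if "score2_max" in spec and dose <= spec["score2_max"]:
            s = 2
        elif "score3_max" in spec and dose <= spec["score3_max"]:
            s = 3
        else:
            s = 4
        # worst-over-window semantics: the segment counts at t while it
        # overlaps (t - window, t], i.e. start <= t and end > t - window
        active = (start <= times) & (end > times - window)
        scores = np.where(active, np.maximum(scores, s), scores)
    return scores.astype(int)


def sofa_scores(timeline: PatientTimeline, times: Sequence[float], window: float = 24.0) -> dict:
    """Vectorized SOFA subscores and totals at query ``times``.

    Each subscore reads the worst value of its organ inputs over the trailing
    ``window`` hours; organ systems with no observation in the window score 0
    (dysfunction is never asserted without evidence). The respiration score
    uses PaO2/FiO2 evaluated at PaO2 draw times with carried-forward FiO2
    (room air 0.21 when FiO2 was never charted).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out: dict[str, np.ndarray] = {}

    pao2_t, pao2_v = timeline.times_values("pao2")
    if len(pao2_t):
        fio2 = timeline.values_at("fio2", pao2_t)
        fio2 = np.where(np.isnan(fio2), 0.21, np.maximum(fio2, 0.21))
        ratio = pao2_v / fio2
        lo = np.searchsorted(pao2_t, times - window, side="right")
        hi = np.searchsorted(pao2_t, times, side="right")
        from .ehr import _range_extremum

        worst_ratio = _range_extremum(ratio, lo, hi, "min")
    else:
        worst_ratio = np.full(len(times), np.nan)
    out["respiration"] = _band_scores(
        worst_ratio, _SOFA["respiration"]["thresholds"], "lt"
    )
    out["coagulation"] = _band_scores(
        timeline.extrema_in_window("platelets", times, window, "min"),
        _SOFA["coagulation"]["thresholds"],
        "lt",
    )
    out["liver"] = _band_scores(
        timeline.extrema_in_window("bilirubin", times, window, "max"),
        _SOFA["liver"]["thresholds"],
        "ge",
    )
    out["cns"] = _band_scores(
        timeline.extrema_in_window("gcs", times, window, "min"),
        _SOFA["cns"]["thresholds"],
        "lt",
    )
    out["renal"] = _band_scores(
        timeline.extrema_in_window("creatinine", times, window, "max"),
        _SOFA["renal"]["thresholds"],
        "ge",
    )
    out["cardiovascular"] = _cardiovascular_scores(timeline, times, window)
    out["total"] = sum(out[s] for s in SOFA_SYSTEMS)
    return out


def sofa_at(timeline: PatientTimeline, t: float, window: float = 24.0) -> SofaScore:
    """SOFA score at a single time ``t`` from worst in-window values."""
    s = sofa_scores(timeline, [t], window=window)
    return SofaScore(
        time=float(t),
        respiration=int(s["respiration"][0]),
        coagulation=int(s["coagulation"][0]),
        liver=int(s["liver"][0]),
        cardiovascular=int(s["cardiovascular"][0]),
        cns=int(s["cns"][0]),
        renal=int(s["renal"][0]),
    )


# -- SIRS -------------------------------------------------------------------


def sirs_counts(timeline: PatientTimeline, times: Sequence[float]) -> np.ndarray:
    """SIRS criterion count (0-4) at each time, on current carried-forward values."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    temp = timeline.values_at("temperature", times)
    hr = timeline.values_at("heart_rate", times)
    rr = timeline.values_at("respiratory_rate", times)
    paco2 = timeline.values_at("paco2", times)
    wbc = timeline.values_at("wbc", times)

    c = _SIRS
    with np.errstate(invalid="ignore"):
        count = (
            ((temp > c["temperature"]["high"]) | (temp < c["temperature"]["low"])).astype(int)
            + (hr > c["heart_rate"]["high"]).astype(int)
            + (
                (rr > c["respiratory"]["respiratory_rate_high"])
                | (paco2 < c["respiratory"]["paco2_low"])
            ).astype(int)
            + ((wbc > c["wbc"]["high"]) | (wbc < c["wbc"]["low"])).astype(int)
        )
    return count


def sirs_at(timeline: PatientTimeline, t: float) -> int:
    return int(sirs_counts(timeline, [t])[0])


# -- label sequences --------------------------------------------------------


def _label_grid(timeline: PatientTimeline) -> np.ndarray:
    ev = [e.time for e in timeline.events]
    tr = [t.time for t in timeline.treatments]
    return np.unique(np.asarray(ev + tr, dtype=float))


def sepsis3_labels(
    timeline: PatientTimeline,
    fluid_rule: FluidRule | None = None,
    dialect: str = "concomitant",
    infection_params: InfectionParams | None = None,
    sofa_window: float = 24.0,
    lactate_threshold: float = 2.0,
) -> ClinicalStateSequence:
    """Sepsis-3 state labels at every unique event/treatment timestamp.

    sepsis: suspected infection established and SOFA total >= 2.
    septic shock: sepsis, plus adequate fluid resuscitation per ``fluid_rule``,
    an active vasopressor (the operational reading of "requires vasopressors
    to maintain MAP >= 65"), and carried-forward lactate strictly > 2 mmol/L.
    """
    fluid_rule = fluid_rule or FluidRule()
    times = _label_grid(timeline)
    if len(times) == 0:
        raise ValueError(f"patient {timeline.patient_id!r} has no events to label")
    t_si = suspected_infection_times(timeline, dialect=dialect, params=infection_params)

    labels = np.full(len(times), NON_SEPSIS, dtype=object)
    if t_si is not None:
        total = sofa_scores(timeline, times, window=sofa_window)["total"]
        sepsis_mask = (times >= t_si) & (total >= 2)
        labels[sepsis_mask] = SEPSIS

        fluids_ok = (
            timeline.fluid_volume_in_window(times, fluid_rule.window)
            >= fluid_rule.ml_per_kg * timeline.weight_kg
        )
        vaso = timeline.vasopressor_active(times)
        lact = timeline.values_at("lactate", times)
        with np.errstate(invalid="ignore"):
            lact_ok = ~np.isnan(lact) & (lact > lactate_threshold)
        shock_mask = sepsis_mask & fluids_ok & vaso & lact_ok
        labels[shock_mask] = SEPTIC_SHOCK

    seq = ClinicalStateSequence(
        patient_id=timeline.patient_id,
        times=times,
        labels=labels,
        criteria="sepsis3",
        suspected_infection_time=t_si,
        shock_onset=None,
        observation_end=timeline.observation_end,
    )
    seq.shock_onset = shock_onset_time(seq)
    return seq


def sepsis2_labels(
    timeline: PatientTimeline,
    fluid_rule: FluidRule | None = None,
    dialect: str = "concomitant",
    infection_params: InfectionParams | None = None,
    map_threshold: float = 65.0,
) -> ClinicalStateSequence:
    """Sepsis-2 state labels with sepsis and severe sepsis aggregated.

    aggregate sepsis state: SIRS >= 2 (on current carried-forward values) with
    suspected infection. septic shock: additionally, hypotension (carried-
    forward MAP < 65 mmHg) despite fluid-rule-adequate resuscitation, or an
    active vasopressor. Because SIRS reads instantaneous values, these labels
    fluctuate by construction.
    """
    fluid_rule = fluid_rule or FluidRule()
    times = _label_grid(timeline)
    if len(times) == 0:
        raise ValueError(f"patient {timeline.patient_id!r} has no events to label")
    t_si = suspected_infection_times(timeline, dialect=dialect, params=infection_params)

    labels = np.full(len(times), NON_SEPSIS, dtype=object)
    if t_si is not None:
        sirs = sirs_counts(timeline, times)
        sepsis_mask = (times >= t_si) & (sirs >= 2)
        labels[sepsis_mask] = SEPSIS_AGGREGATE

        fluids_ok = (
            timeline.fluid_volume_in_window(times, fluid_rule.window)
            >= fluid_rule.ml_per_kg * timeline.weight_kg
        )
        map_now = timeline.values_at("map", times)
        with np.errstate(invalid="ignore"):
            hypotensive = ~np.isnan(map_now) & (map_now < map_threshold)
        vaso = timeline.vasopressor_active(times)
        shock_mask = sepsis_mask & (vaso | (hypotensive & fluids_ok))
        labels[shock_mask] = SEPTIC_SHOCK

    seq = ClinicalStateSequence(
        patient_id=timeline.patient_id,
        times=times,
        labels=labels,
        criteria="sepsis2",
        suspected_infection_time=t_si,
        shock_onset=None,
        observation_end=timeline.observation_end,
    )
    seq.shock_onset = shock_onset_time(seq)
    return seq


def shock_onset_time(sequence: ClinicalStateSequence) -> float | None:
    """First timestamp labeled septic shock, or None if the patient never enters it."""
    hits = np.nonzero(sequence.labels == SEPTIC_SHOCK)[0]
    return float(sequence.times[hits[0]]) if len(hits) else None


def dwell_statistics(sequences: Iterable[ClinicalStateSequence]) -> StabilityStats:
    """Dwell-time distributions per state and label-change counts per patient.

    A dwell is the duration of a contiguous run of one label, ending at the
    next label-change timestamp; the final run ends at ``observation_end``.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("dwell_statistics requires at least one sequence")
    dwell: dict[str, list[float]] = {}
    changes = []
    for seq in sequences:
        labels, times = seq.labels, seq.times
        if len(labels) == 0:
            raise ValueError(f"empty label sequence for patient {seq.patient_id!r}")
        change_idx = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        changes.append(len(change_idx))
        starts = np.concatenate([[0], change_idx])
        ends_t = np.concatenate([times[change_idx], [seq.observation_end]])
        for s, e_t in zip(starts, ends_t):
            dwell.setdefault(str(labels[s]), []).append(float(e_t - times[s]))
    dwell_arr = {k: np.asarray(v, dtype=float) for k, v in dwell.items()}
    changes = np.asarray(changes, dtype=float)
    return StabilityStats(
        dwell_times=dwell_arr,
        mean_dwell={k: float(v.mean()) for k, v in dwell_arr.items()},
        median_dwell={k: float(np.median(v)) for k, v in dwell_arr.items()},
        label_changes=changes,
        mean_changes=float(changes.mean()),
        median_changes=float(np.median(changes)),
    )
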