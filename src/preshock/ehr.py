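"""Data model and I/O for long-format EHR event streams.

ICU records arrive as irregular timestamp--value pairs per patient. This
module provides the in-memory containers used by every downstream stage
(:class:`PatientTimeline` and friends), CSV loading with a configurable
feature dictionary and plausibility screening, and the two time queries the
clinical criteria are built from:

* carry-forward lookup (``value_at``): the most recent observation at or
  before a query time -- the standard last-observation-carried-forward
  convention for irregular clinical series;
* windowed extrema (``extremum_in_window``): the worst observed value over a
  trailing window, as used by SOFA scoring ("worst value over the preceding
  24 hours").

Time is real-valued hours relative to each patient's first recorded event.
Input files may carry absolute datetimes; these are converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TREATMENT_KINDS = ("antibiotic_order", "culture_order", "vasopressor", "fluid_bolus")
_DOSED_KINDS = ("vasopressor", "fluid_bolus")


def _load_fixture(name: str):
    with (resources.files("preshock") / "data" / name).open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class EventRecord:
    """One timestamped observation of a canonical feature."""

    patient_id: str
    time: float  # hours since the patient's first observation, >= 0
    feature: str
    value: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.value):
            raise ValueError(f"event value must be finite, got {self.value}")


@dataclass(frozen=True)
class TreatmentEvent:
    """A treatment order or administration.

    ``dose`` is required for vasopressors (ug/kg/min, norepinephrine unless
    ``agent`` says otherwise; 0 marks a stop) and fluid boluses (mL).
    """

    patient_id: str
    time: float
    kind: str
    dose: float | None = None
    agent: str | None = None

    def __post_init__(self):
        if self.kind not in TREATMENT_KINDS:
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"treatment time must be finite and >= 0, got {self.time}")
        if self.kind in _DOSED_KINDS:
            if self.dose is None or not np.isfinite(self.dose) or self.dose < 0:
                raise ValueError(f"{self.kind} requires a finite dose >= 0")


class FeatureDictionary:
    """Maps raw item codes to canonical feature names, units and bounds.

    ``entries`` is ``{item_code: {feature, unit, lower_bound, upper_bound}}``.
    The shipped default (:meth:`default`) uses canonical names as codes and
    carries the package's editable plausibility bounds.
    """

    def __init__(self, entries: Mapping[str, Mapping]):
        self._entries: dict[str, dict] = {}
        self._by_feature: dict[str, dict] = {}
        for code, raw in entries.items():
            entry = dict(raw)
            if "feature" not in entry:
                raise ValueError(f"dictionary entry for {code!r} lacks a 'feature' name")
            entry.setdefault("lower_bound", -np.inf)
            entry.setdefault("upper_bound", np.inf)
            self._entries[str(code)] = entry
            self._by_feature.setdefault(entry["feature"], entry)

    @classmethod
    def default(cls) -> "FeatureDictionary":
        return cls(_load_fixture("feature_dictionary.yaml"))

    @classmethod
    def from_yaml(cls, path) -> "FeatureDictionary":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def __contains__(self, code) -> bool:
        return str(code) in self._entries

    def feature_for(self, code) -> str | None:
        entry = self._entries.get(str(code))
        return None if entry is None else entry["feature"]

    def bounds_for_feature(self, feature: str) -> tuple[float, float]:
        entry = self._by_feature.get(feature)
        if entry is None:
            return (-np.inf, np.inf)
        return (float(entry["lower_bound"]), float(entry["upper_bound"]))

    @property
    def canonical_features(self) -> frozenset[str]:
        return frozenset(self._by_feature)


def _range_extremum(values: np.ndarray, lo: np.ndarray, hi: np.ndarray, direction: str) -> np.ndarray:
    """Vectorized range max/min of ``values[lo:hi]`` per query (NaN if empty).

    Uses a sparse table, so large query batches (SOFA over a whole cohort)
    stay O((n + q) log n).
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    op = np.maximum if direction == "max" else np.minimum
    out = np.full(len(lo), np.nan)
    n = len(values)
    if n == 0:
        return out
    valid = hi > lo
    if not valid.any():
        return out
    tables = [np.asarray(values, dtype=float)]
    span = 1
    while 2 * span <= n:
        prev = tables[-1]
        tables.append(op(prev[: len(prev) - span], prev[span:]))
        span *= 2
    length = hi - lo
    levels = np.zeros(len(lo), dtype=int)
    levels[valid] = np.floor(np.log2(length[valid])).astype(int)
    for j in np.unique(levels[valid]):
        mask = valid & (levels == j)
        tab = tables[j]
        out[mask] = op(tab[lo[mask]], tab[hi[mask] - (1 << j)])
    return out


class PatientTimeline:
    """Time-ordered observations and treatments for one patient.

    Events are stably sorted by time; at identical timestamps the later
    record in input order wins for carry-forward queries.
    """

    def __init__(
        self,
        patient_id: str,
        events: Iterable[EventRecord],
        treatments: Iterable[TreatmentEvent] = (),
        weight_kg: float = 70.0,
        observation_end: float | None = None,
        known_features: Iterable[str] | None = None,
    ):
        self.patient_id = str(patient_id)
        if not (np.isfinite(weight_kg) and weight_kg > 0):
            raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
        self.weight_kg = float(weight_kg)
        self.events = sorted(events, key=lambda e: e.time)  # stable
        self.treatments = sorted(treatments, key=lambda e: e.time)
        last = 0.0
        if self.events:
            last = max(last, self.events[-1].time)
        if self.treatments:
            last = max(last, self.treatments[-1].time)
        self.observation_end = last if observation_end is None else float(observation_end)
        if self.observation_end < last:
            raise ValueError(
                f"observation_end {self.observation_end} precedes last event at {last}"
            )

        self._obs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for ev in self.events:
            self._obs.setdefault(ev.feature, ([], []))
        by_feature: dict[str, list] = {f: [] for f in self._obs}
        for ev in self.events:
            by_feature[ev.feature].append((ev.time, ev.value))
        for feat, pairs in by_feature.items():
            arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
            self._obs[feat] = (arr[:, 0], arr[:, 1])

        self._treat: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        for kind in TREATMENT_KINDS:
            rows = [t for t in self.treatments if t.kind == kind]
            times = np.asarray([t.time for t in rows], dtype=float)
            doses = np.asarray(
                [t.dose if t.dose is not None else np.nan for t in rows], dtype=float
            )
            self._treat[kind] = (times, doses, [t.agent for t in rows])

        if known_features is None:
            default = FeatureDictionary.default().canonical_features
            self._known = frozenset(default) | frozenset(self._obs)
        else:
            self._known = frozenset(known_features) | frozenset(self._obs)

    # -- observations -------------------------------------------------------

    def _check_feature(self, feature: str) -> None:
        if feature not in self._known:
            raise KeyError(f"unknown canonical feature {feature!r}")

    def observed_features(self) -> frozenset[str]:
        return frozenset(self._obs)

    def times_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        self._check_feature(feature)
        return self._obs.get(feature, (np.empty(0), np.empty(0)))

    def values_at(
        self, feature: str, times: Sequence[float], expiry: float | None = None
    ) -> np.ndarray:
        """Carry-forward values at query ``times`` (NaN where no prior obs)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        ftimes, fvalues = self.times_values(feature)
        out = np.full(len(times), np.nan)
        if len(ftimes) == 0:
            return out
        idx = np.searchsorted(ftimes, times, side="right") - 1
        hit = idx >= 0
        out[hit] = fvalues[idx[hit]]
        if expiry is not None:
            stale = hit & (times - ftimes[np.clip(idx, 0, None)] > expiry)
            out[stale] = np.nan
        return out

    def value_at(self, feature: str, t: float, expiry: float | None = None) -> float | None:
        v = self.values_at(feature, [t], expiry=expiry)[0]
        return None if np.isnan(v) else float(v)

    def extrema_in_window(
        self, feature: str, t_ends: Sequence[float], width: float, direction: str = "max"
    ) -> np.ndarray:
        """Extremum of observed values with time in ``(t_end - width, t_end]``."""
        if width <= 0:
            raise ValueError(f"width must be > 0, got {width}")
        t_ends = np.atleast_1d(np.asarray(t_ends, dtype=float))
        ftimes, fvalues = self.times_values(feature)
        lo = np.searchsorted(ftimes, t_ends - width, side="right")
        hi = np.searchsorted(ftimes, t_ends, side="right")
        return _range_extremum(fvalues, lo, hi, direction)

    def extremum_in_window(
        self, feature: str, t_end: float, width: float, direction: str = "max"
    ) -> float | None:
        v = self.extrema_in_window(feature, [t_end], width, direction)[0]
        return None if np.isnan(v) else float(v)

    def unique_event_times(self) -> np.ndarray:
        return np.unique(np.asarray([e.time for e in self.events], dtype=float))

    # -- treatments ---------------------------------------------------------

    def treatment_times(self, kind: str) -> tuple[np.ndarray, np.ndarray, list]:
        if kind not in TREATMENT_KINDS:
            raise ValueError(f"unknown treatment kind {kind!r}")
        return self._treat[kind]

    def fluid_volume_in_window(self, t_ends: Sequence[float], width: float = 24.0) -> np.ndarray:
        """Cumulative bolus volume (mL) administered in ``(t_end - width, t_end]``."""
        t_ends = np.atleast_1d(np.asarray(t_ends, dtype=float))
        times, doses, _ = self._treat["fluid_bolus"]
        if len(times) == 0:
            return np.zeros(len(t_ends))
        csum = np.concatenate([[0.0], np.cumsum(doses)])
        hi = np.searchsorted(times, t_ends, side="right")
        lo = np.searchsorted(times, t_ends - width, side="right")
        return csum[hi] - csum[lo]

    def vasopressor_intervals(self) -> list[tuple[float, float, float, str]]:
        """Active-dose segments ``(start, end, dose, agent)``; dose-0 events stop an agent."""
        times, doses, agents = self._treat["vasopressor"]
        by_agent: dict[str, list[tuple[float, float]]] = {}
        for t, d, a in zip(times, doses, agents):
            by_agent.setdefault(a or "norepinephrine", []).append((t, d))
        out = []
        for agent, rows in by_agent.items():
            for i, (t, d) in enumerate(rows):
                end = rows[i + 1][0] if i + 1 < len(rows) else np.inf
                if d > 0:
                    out.append((t, end, d, agent))
        return out

    def vasopressor_active(self, times: Sequence[float]) -> np.ndarray:
        """Boolean mask: some vasopressor dose > 0 carried forward at each time."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.zeros(len(times), dtype=bool)
        for start, end, _dose, _agent in self.vasopressor_intervals():
            out |= (times >= start) & (times < end)
        return out

    def __repr__(self):
        return (
            f"PatientTimeline({self.patient_id!r}, {len(self.events)} events, "
            f"{len(self.treatments)} treatments, end={self.observation_end:.1f}h)"
        )


# -- module-level operation wrappers ----------------------------------------


def value_at(timeline: PatientTimeline, feature: str, t: float, expiry: float | None = None):
    """Most recent observation of ``feature`` at time <= ``t`` (None if none)."""
    return timeline.value_at(feature, t, expiry=expiry)


def extremum_in_window(
    timeline: PatientTimeline, feature: str, t_end: float, width: float, direction: str = "max"
):
    """Extremum of observations in the half-open window ``(t_end - width, t_end]``."""
    return timeline.extremum_in_window(feature, t_end, width, direction)


# -- I/O --------------------------------------------------------------------

_EVENT_COLUMNS = ("patient_id", "time", "item_code", "value")
_TREATMENT_COLUMNS = ("patient_id", "time", "kind", "dose", "agent")
_META_COLUMNS = ("patient_id", "weight_kg", "observation_end")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing required column(s): {', '.join(missing)}")


def _times_to_hours(frames: list[pd.DataFrame]) -> list[np.ndarray]:
    """Convert 'time' columns to float hours, sharing per-patient origins.

    Accepts float hours directly, or ISO datetimes converted to hours since
    each patient's earliest record across all provided frames.
    """
    numeric = [pd.to_numeric(df["time"], errors="coerce") for df in frames]
    if all(num.notna().all() for num, df in zip(numeric, frames) if len(df)):
        return [num.to_numpy(dtype=float) for num in numeric]
    stamps = [pd.to_datetime(df["time"], errors="raise") for df in frames]
    origin = (
        pd.concat(
            [pd.DataFrame({"patient_id": df["patient_id"], "stamp": s}) for df, s in zip(frames, stamps)]
        )
        .groupby("patient_id")["stamp"]
        .min()
    )
    out = []
    for df, s in zip(frames, stamps):
        base = df["patient_id"].map(origin)
        out.append(((s - base).dt.total_seconds() / 3600.0).to_numpy(dtype=float))
    return out


def load_events(
    events_path,
    treatments_path=None,
    meta_path=None,
    dictionary: FeatureDictionary | None = None,
    unknown_codes: str = "drop",
    return_report: bool = False,
):
    """Load long-format CSVs into a dict of :class:`PatientTimeline`.

    Out-of-bounds values and non-numeric rows are dropped (counts logged and
    available via ``return_report=True``). Unknown item codes are dropped or
    raised per ``unknown_codes`` ('drop' | 'raise'). A patient present in the
    events file but absent from the metadata file is an error.
    """
    if dictionary is None:
        dictionary = FeatureDictionary.default()
    if unknown_codes not in ("drop", "raise"):
        raise ValueError("unknown_codes must be 'drop' or 'raise'")

    ev = pd.read_csv(
        events_path, dtype={"patient_id": str, "item_code": str}, float_precision="round_trip"
    )
    _require_columns(ev, _EVENT_COLUMNS, "events")
    report = {"rows_nonnumeric": 0, "rows_unknown_code": 0, "rows_out_of_bounds": 0}

    values = pd.to_numeric(ev["value"], errors="coerce")
    bad = values.isna()
    report["rows_nonnumeric"] = int(bad.sum())
    if bad.any():
        logger.warning("dropped %d event rows with non-numeric values", bad.sum())
    ev = ev.loc[~bad].assign(value=values[~bad])

    features = ev["item_code"].map(dictionary.feature_for)
    unknown = features.isna()
    if unknown.any():
        if unknown_codes == "raise":
            codes = sorted(ev.loc[unknown, "item_code"].unique())
            raise KeyError(f"unknown item code(s): {', '.join(map(str, codes))}")
        report["rows_unknown_code"] = int(unknown.sum())
        logger.warning("dropped %d event rows with unknown item codes", unknown.sum())
    ev = ev.loc[~unknown].assign(feature=features[~unknown])

    tr = None
    if treatments_path is not None:
        tr = pd.read_csv(
            treatments_path,
            dtype={"patient_id": str, "kind": str, "agent": str},
            float_precision="round_trip",
        )
        _require_columns(tr, ("patient_id", "time", "kind"), "treatments")
        if "dose" not in tr.columns:
            tr["dose"] = np.nan
        if "agent" not in tr.columns:
            tr["agent"] = None

    frames = [ev] if tr is None else [ev, tr]
    hours = _times_to_hours(frames)
    ev = ev.assign(time=hours[0])
    if tr is not None:
        tr = tr.assign(time=hours[1])

    lo = ev["feature"].map(lambda f: dictionary.bounds_for_feature(f)[0])
    hi = ev["feature"].map(lambda f: dictionary.bounds_for_feature(f)[1])
    oob = (ev["value"] < lo) | (ev["value"] > hi)
    report["rows_out_of_bounds"] = int(oob.sum())
    if oob.any():
        logger.warning("dropped %d event rows outside plausibility bounds", oob.sum())
    ev = ev.loc[~oob]

    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, dtype={"patient_id": str}, float_precision="round_trip")
        _require_columns(meta, ("patient_id", "weight_kg"), "metadata")
        meta = meta.set_index("patient_id")
        for pid in ev["patient_id"].unique():
            if pid not in meta.index:
                raise KeyError(f"patient {pid!r} present in events but missing from metadata")

    known = dictionary.canonical_features
    timelines: dict[str, PatientTimeline] = {}
    patient_ids = list(dict.fromkeys(ev["patient_id"]))
    if meta is not None:
        patient_ids += [p for p in meta.index if p not in patient_ids]
    for pid in patient_ids:
        sub = ev[ev["patient_id"] == pid]
        events = [
            EventRecord(pid, t, f, v)
            for t, f, v in zip(sub["time"], sub["feature"], sub["value"])
        ]
        treatments = []
        if tr is not None:
            tsub = tr[tr["patient_id"] == pid]
            for _, row in tsub.iterrows():
                dose = row["dose"]
                treatments.append(
                    TreatmentEvent(
                        pid,
                        float(row["time"]),
                        row["kind"],
                        dose=None if pd.isna(dose) else float(dose),
                        agent=None if pd.isna(row["agent"]) else str(row["agent"]),
                    )
                )
        weight, obs_end = 70.0, None
        if meta is not None:
            weight = float(meta.loc[pid, "weight_kg"])
            if "observation_end" in meta.columns and pd.notna(meta.loc[pid, "observation_end"]):
                obs_end = float(meta.loc[pid, "observation_end"])
        timelines[pid] = PatientTimeline(
            pid, events, treatments, weight_kg=weight, observation_end=obs_end, known_features=known
        )
    if return_report:
        return timelines, report
    return timelines


def timelines_to_frames(timelines: Mapping[str, PatientTimeline]):
    """Serialize timelines to the three canonical DataFrames (events, treatments, metadata)."""
    ev_rows, tr_rows, meta_rows = [], [], []
    for pid, tl in timelines.items():
        for e in tl.events:
            ev_rows.append((pid, e.time, e.feature, e.value))
        for t in tl.treatments:
            tr_rows.append((pid, t.time, t.kind, t.dose, t.agent))
        meta_rows.append((pid, tl.weight_kg, tl.observation_end))
    events = pd.DataFrame(ev_rows, columns=list(_EVENT_COLUMNS)).rename(
        columns={"item_code": "item_code"}
    )
    events.columns = ["patient_id", "time", "item_code", "value"]
    treatments = pd.DataFrame(tr_rows, columns=list(_TREATMENT_COLUMNS))
    meta = pd.DataFrame(meta_rows, columns=list(_META_COLUMNS))
    return events, treatments, meta


def write_cohort(timelines: Mapping[str, PatientTimeline], out_dir, ground_truth=None) -> dict:
    """Write events/treatments/metadata CSVs (plus optional ground truth) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events, treatments, meta = timelines_to_frames(timelines)
    paths = {
        "events": out_dir / "events.csv",
        "treatments": out_dir / "treatments.csv",
        "metadata": out_dir / "metadata.csv",
    }
    events.to_csv(paths["events"], index=False)
    treatments.to_csv(paths["treatments"], index=False)
    meta.to_csv(paths["metadata"], index=False)
    if ground_truth is not None:
        paths["ground_truth"] = out_dir / "ground_truth.csv"
        ground_truth.to_frame().to_csv(paths["ground_truth"], index=False)
    return paths
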