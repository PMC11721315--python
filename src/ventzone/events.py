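"""Setting-change interventions and oxygenation-alarm episodes.

A *raw change* is any breath whose set PEEP or set FiO2 differs from the
previous breath by at least a per-parameter threshold (defaults: PEEP
0.5 cm H2O, FiO2 1 percentage point — below that is telemetry jitter).
Consecutive raw changes of the same parameter in the same direction closer
together than a coalescence window (default 60 s) merge into a single
intervention spanning the first old value to the last new value: a clinician
titrating FiO2 over a few breaths is one intervention, not five.

The origin of an intervention is read from the automation-controller status
at the change breath: ``manual`` or ``frozen`` count as manual (a frozen
controller implies clinician override), ``automated`` as automated.

An alarm episode is a maximal run of breaths with the oxygenation-alarm flag
set; runs separated by a gap of at most one non-alarmed breath merge.  The
episode's duration runs from its first breath to the end of its last breath.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import DEFAULT_DURATION_CAP_S, breath_durations
from .io import PatientManifest

DEFAULT_PEEP_THRESHOLD = 0.5   # cm H2O
DEFAULT_FIO2_THRESHOLD = 1.0   # percentage points
DEFAULT_COALESCENCE_WINDOW_S = 60.0


@dataclasses.dataclass(frozen=True)
class InterventionEvent:
    """One (possibly coalesced) change of a set ventilator parameter."""

    patient_id: str
    time: float
    parameter: str  # "PEEP" | "FiO2"
    old_value: float
    new_value: float
    origin: str  # "manual" | "automated"


@dataclasses.dataclass(frozen=True)
class AlarmEpisode:
    """One contiguous oxygenation-alarm period."""

    patient_id: str
    start: float
    end: float

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0


def _detect_parameter_changes(
    times: np.ndarray,
    values: np.ndarray,
    controller: np.ndarray,
    parameter: str,
    threshold: float,
    window_s: float,
    patient_id: str,
) -> list[InterventionEvent]:
    deltas = np.diff(values)
    idx = np.flatnonzero(np.abs(deltas) >= threshold) + 1  # breath of the change
    events: list[InterventionEvent] = []
    group: list[int] = []

    def flush() -> None:
        if not group:
            return
        first, last = group[0], group[-1]
        origin = "manual" if controller[first] in ("manual", "frozen") else "automated"
        events.append(InterventionEvent(
            patient_id=patient_id,
            time=float(times[first]),
            parameter=parameter,
            old_value=float(values[first - 1]),
            new_value=float(values[last]),
            origin=origin,
        ))

    for i in idx:
        if group:
            prev = group[-1]
            same_dir = np.sign(deltas[i - 1]) == np.sign(deltas[prev - 1])
            close = (times[i] - times[prev]) < window_s
            if same_dir and close:
                group.append(int(i))
                continue
            flush()
            group = []
        group.append(int(i))
    flush()
    return events


def detect_setting_changes(
    frame: pd.DataFrame,
    patient_id: str = "",
    peep_threshold: float = DEFAULT_PEEP_THRESHOLD,
    fio2_threshold: float = DEFAULT_FIO2_THRESHOLD,
    window_s: float = DEFAULT_COALESCENCE_WINDOW_S,
) -> list[InterventionEvent]:
    """Extract PEEP and FiO2 interventions from a canonical breath frame.

    PEEP and FiO2 changes are counted separately; a near-simultaneous change
    of both parameters yields two events.
    """
    if len(frame) < 2:
        return []
    times = frame["time"].to_numpy(float)
    controller = frame["controller"].to_numpy(object)
    events: list[InterventionEvent] = []
    for parameter, column, threshold in (
            ("PEEP", "set_peep", peep_threshold),
            ("FiO2", "set_fio2", fio2_threshold)):
        events.extend(_detect_parameter_changes(
            times, frame[column].to_numpy(float), controller,
            parameter, threshold, window_s, patient_id))
    events.sort(key=lambda e: (e.time, e.parameter))
    return events


def detect_alarm_episodes(
    frame: pd.DataFrame,
    patient_id: str = "",
    max_gap_breaths: int = 1,
    cap_s: float = DEFAULT_DURATION_CAP_S,
) -> list[AlarmEpisode]:
    """Extract alarm episodes; runs with a gap of <= ``max_gap_breaths`` merge."""
    if len(frame) == 0:
        return []
    alarm = frame["alarm"].to_numpy(bool)
    if not alarm.any():
        return []
    times = frame["time"].to_numpy(float)
    dur = breath_durations(times, cap_s=cap_s) if len(times) > 1 else np.array([np.nan])

    idx = np.flatnonzero(alarm)
    # split where the index gap exceeds max_gap_breaths + 1 consecutive slots
    breaks = np.flatnonzero(np.diff(idx) > max_gap_breaths + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    episodes = []
    for s, e in zip(starts, ends):
        first, last = int(idx[s]), int(idx[e])
        end_time = times[last] + (dur[last] if np.isfinite(dur[last]) else 0.0)
        episodes.append(AlarmEpisode(patient_id=patient_id,
                                     start=float(times[first]),
                                     end=float(end_time)))
    return episodes


def count_events_per_phase(
    events: Sequence[InterventionEvent],
    episodes: Sequence[AlarmEpisode],
    manifest: PatientManifest,
) -> pd.DataFrame:
    """Per-phase intervention counts and alarm burden for one patient.

    Events are assigned by timestamp to half-open phase windows; alarm
    episodes straddling a window boundary are split there and their duration
    apportioned.  Returns one row per phase label (automated, conventional,
    washout) with columns ``n_manual, n_automated, n_alarms, alarm_minutes``.
    """
    windows = [
        (manifest.phase_mode["phase1"], manifest.phase1_start, manifest.phase1_end),
        ("washout", manifest.phase1_end, manifest.phase2_start),
        (manifest.phase_mode["phase2"], manifest.phase2_start, manifest.phase2_end),
    ]
    rows = []
    for label, start, end in windows:
        n_manual = sum(1 for e in events
                       if start <= e.time < end and e.origin == "manual")
        n_automated = sum(1 for e in events
                          if start <= e.time < end and e.origin == "automated")
        n_alarms = 0
        minutes = 0.0
        for ep in episodes:
            lo, hi = max(ep.start, start), min(ep.end, end)
            if hi > lo:
                n_alarms += 1
                minutes += (hi - lo) / 60.0
        rows.append({
            "patient_id": manifest.patient_id, "phase": label,
            "n_manual": n_manual, "n_automated": n_automated,
            "n_alarms": n_alarms, "alarm_minutes": minutes,
        })
    return pd.DataFrame(rows)
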