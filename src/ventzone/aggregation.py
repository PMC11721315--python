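"""Phase segmentation and per-patient zone-occupancy endpoints.

The crossover design gives each patient two treatment phases separated by a
washout.  Records are assigned to phase windows by timestamp using half-open
intervals ``[start, end)``; washout breaths are carried in their own segment
but excluded from every endpoint.

Two families of endpoints are computed per phase and per classification view
(combined zone, SpO2-only, PEEP/FiO2-only):

* percentage of breaths in zone
  = 100 x (breaths in zone) / (classified breaths);
* percentage of time in zone, where each breath's duration is the interval
  to the next breath, capped (default 15 s) so signal dropouts cannot
  dominate, and the final breath inherits the segment's median duration.

Unclassified breaths are excluded from denominators; the unclassified
fraction is reported alongside.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import zones
from .errors import ValidationError
from .io import PatientManifest

#: default cap on a single breath's duration, seconds
DEFAULT_DURATION_CAP_S = 15.0

VIEWS = ("combined", "spo2", "pf")
_VIEW_COLUMN = {"combined": "combined", "spo2": "spo2_zone", "pf": "pf_zone"}


@dataclasses.dataclass
class PhaseSegment:
    """A contiguous slice of one patient's log inside one phase window."""

    patient_id: str
    phase_label: str  # "automated" | "conventional" | "washout"
    frame: pd.DataFrame
    start: float
    end: float


def segment_phases(
    frame: pd.DataFrame,
    manifest: PatientManifest,
) -> tuple[list[PhaseSegment], int]:
    """Split a log into phase-1 / washout / phase-2 segments.

    Returns the segments (in time order; washout only if non-empty design
    window) and the number of records outside all windows, which are dropped.
    """
    t = frame["time"].to_numpy(float)
    windows = [
        (manifest.phase_mode["phase1"], manifest.phase1_start, manifest.phase1_end),
        ("washout", manifest.phase1_end, manifest.phase2_start),
        (manifest.phase_mode["phase2"], manifest.phase2_start, manifest.phase2_end),
    ]
    segments: list[PhaseSegment] = []
    assigned = np.zeros(len(frame), dtype=bool)
    for label, start, end in windows:
        if end <= start:  # zero-length washout is legal
            continue
        mask = (t >= start) & (t < end)
        assigned |= mask
        segments.append(PhaseSegment(
            patient_id=manifest.patient_id,
            phase_label=label,
            frame=frame.loc[mask].reset_index(drop=True),
            start=start, end=end,
        ))
    return segments, int((~assigned).sum())


def breath_durations(times: np.ndarray,
                     cap_s: float = DEFAULT_DURATION_CAP_S) -> np.ndarray:
    """Per-breath durations: interval to the next breath, capped.

    The final breath has no successor and inherits the median of the other
    capped durations.  A single-breath input yields ``[nan]`` with a warning.
    """
    times = np.asarray(times, float)
    n = len(times)
    if n == 0:
        return np.empty(0)
    if n == 1:
        warnings.warn("single-breath segment: breath duration undefined",
                      stacklevel=2)
        return np.array([np.nan])
    d = np.minimum(np.diff(times), cap_s)
    return np.append(d, np.median(d))


def percent_breaths_in_zone(labels: Sequence[str] | np.ndarray, zone: str) -> float:
    """Share of classified breaths carrying ``zone``, in percent.

    Returns NaN (not zero) when no breath is classified.
    """
    labels = np.asarray(labels, dtype=object)
    classified = labels != zones.UNCLASSIFIED
    n = int(classified.sum())
    if n == 0:
        return float("nan")
    return 100.0 * float((labels[classified] == zone).sum()) / n


def percent_time_in_zone(times: np.ndarray,
                         labels: Sequence[str] | np.ndarray,
                         zone: str,
                         cap_s: float = DEFAULT_DURATION_CAP_S) -> float:
    """Share of classified breath-time spent in ``zone``, in percent."""
    times = np.asarray(times, float)
    labels = np.asarray(labels, dtype=object)
    if len(times) != len(labels):
        raise ValidationError("times and labels must be parallel")
    if len(times) < 2:
        warnings.warn("segment too short for time-in-zone", stacklevel=2)
        return float("nan")
    dur = breath_durations(times, cap_s=cap_s)
    classified = labels != zones.UNCLASSIFIED
    total = float(dur[classified].sum())
    if total <= 0.0:
        return float("nan")
    return 100.0 * float(dur[classified & (labels == zone)].sum()) / total


@dataclasses.dataclass
class PhaseEndpoints:
    """All occupancy endpoints of one patient-phase."""

    n_breaths: int
    n_classified: int
    unclassified_fraction: float
    pct_breaths: dict[str, dict[str, float]]  # view -> zone -> percent
    pct_time: dict[str, dict[str, float]]


@dataclasses.dataclass
class PatientSummary:
    """Per-patient endpoint values for both arms, feeding the paired stats."""

    patient_id: str
    phases: dict[str, PhaseEndpoints]  # "automated" / "conventional"


def _phase_endpoints(segment: PhaseSegment, views: pd.DataFrame,
                     cap_s: float) -> PhaseEndpoints:
    labels_combined = views["combined"].to_numpy()
    n = len(views)
    n_classified = int((labels_combined != zones.UNCLASSIFIED).sum())
    times = segment.frame["time"].to_numpy(float)
    pct_breaths: dict[str, dict[str, float]] = {}
    pct_time: dict[str, dict[str, float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short segments yield NaN quietly
        for view in VIEWS:
            lab = views[_VIEW_COLUMN[view]].to_numpy()
            pct_breaths[view] = {z: percent_breaths_in_zone(lab, z) for z in zones.ZONES}
            pct_time[view] = {z: percent_time_in_zone(times, lab, z, cap_s=cap_s)
                              for z in zones.ZONES}
    return PhaseEndpoints(
        n_breaths=n,
        n_classified=n_classified,
        unclassified_fraction=(n - n_classified) / n if n else float("nan"),
        pct_breaths=pct_breaths,
        pct_time=pct_time,
    )


def summarize_patient(segments: Sequence[PhaseSegment],
                      table: zones.ZoneTable,
                      cap_s: float = DEFAULT_DURATION_CAP_S) -> PatientSummary:
    """Classify and aggregate one patient's segments into a PatientSummary.

    Washout segments are skipped.  A phase absent from the log yields an
    endpoint block with ``n_breaths = 0`` and NaN percentages.
    """
    if not segments:
        raise ValidationError("summarize_patient needs at least one segment")
    patient_id = segments[0].patient_id
    empty = PhaseEndpoints(
        n_breaths=0, n_classified=0, unclassified_fraction=float("nan"),
        pct_breaths={v: {z: float("nan") for z in zones.ZONES} for v in VIEWS},
        pct_time={v: {z: float("nan") for z in zones.ZONES} for v in VIEWS})
    phases: dict[str, PhaseEndpoints] = {"automated": empty, "conventional": empty}
    for seg in segments:
        if seg.phase_label == "washout":
            continue
        views = zones.classify_views(seg.frame, table)
        phases[seg.phase_label] = _phase_endpoints(seg, views, cap_s)
    return PatientSummary(patient_id=patient_id, phases=phases)


def summaries_to_frame(summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    """Tidy frame: one row per patient x phase x view x metric x zone."""
    rows = []
    for s in summaries:
        for phase, ep in s.phases.items():
            for view in VIEWS:
                for metric, store in (("breaths", ep.pct_breaths),
                                      ("time", ep.pct_time)):
                    for zone in zones.ZONES:
                        rows.append({
                            "patient_id": s.patient_id, "phase": phase,
                            "view": view, "metric": metric, "zone": zone,
                            "value": store[view][zone],
                            "n_breaths": ep.n_breaths,
                        })
    return pd.DataFrame(rows)
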