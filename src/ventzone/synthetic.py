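"""Seeded generator of crossover ventilator logs with known ground truth.

The generator reproduces the *statistical* log signature the analysis
assumes, not lung physiology:

* breath timestamps from a jittered renewal process (gamma inter-breath
  intervals at a configurable mean respiratory rate);
* per-breath (SpO2, PEEP, FiO2) triples drawn from the preimage of a target
  oxygenation zone under the shipped zone table, so the classification of
  every generated breath is known by construction.  Zone targets are
  re-drawn per dwell period (default mean 120 s) to create realistic serial
  correlation; a dwell mean of 0 gives i.i.d. per-breath draws;
* sparse manual setting changes in both arms and frequent small automated
  changes in the automated arm, laid down as Poisson processes with a
  minimum spacing that keeps every change an individual detectable event;
* oxygenation-alarm episodes as a Poisson process with exponential
  durations, placed without overlap.

Default parameter values mirror the crossover study conditions the package
analyses: 53 patients, two 3 h phases, a 30 min washout, 1:1 alternating
first mode, and per-arm event rates on the scale reported for automated vs
conventional ventilation.

Reproducibility: one global seed; patient ``i`` uses the substream
``SeedSequence(entropy=seed, spawn_key=(i,))``, so cohorts are reproducible
and patients independent.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as vio
from . import zones
from .errors import ConfigurationError

ARMS = ("automated", "conventional")


@dataclasses.dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    n_patients: int = 53
    phase_minutes: float = 180.0
    washout_minutes: float = 30.0
    rr_mean: float = 18.0          # breaths / min
    rr_jitter: float = 0.2         # CV of the inter-breath interval; 0 = rigid
    #: target (optimal, acceptable, critical) occupancy per arm
    zone_occupancy: dict = dataclasses.field(default_factory=lambda: {
        "automated": (0.46, 0.20, 0.34),
        "conventional": (0.46, 0.21, 0.33),
    })
    #: clinician interventions per hour per arm
    manual_intervention_rate: dict = dataclasses.field(default_factory=lambda: {
        "automated": 1.3 / 3.0,
        "conventional": 2.1 / 3.0,
    })
    #: controller-made setting changes per hour (automated arm only)
    automated_change_rate: float = 33.9 / 3.0
    #: alarm episodes per hour per arm
    alarm_rate: dict = dataclasses.field(default_factory=lambda: {
        "automated": 6.9 / 3.0,
        "conventional": 1.4 / 3.0,
    })
    #: mean alarm-episode duration, seconds, per arm
    alarm_duration_mean_s: dict = dataclasses.field(default_factory=lambda: {
        "automated": 57.0,
        "conventional": 94.0,
    })
    dwell_mean_s: float = 120.0    # mean time between zone re-draws; 0 = i.i.d.
    spo2_missing_rate: float = 0.0
    peep_floor: float = 5.0
    peep_ceiling: float = 12.0
    zone_table: str = "default_v1"
    seed: int = 0

    def __post_init__(self) -> None:
        for arm in ARMS:
            occ = self.zone_occupancy[arm]
            if len(occ) != 3 or abs(sum(occ) - 1.0) > 1e-9 or min(occ) < 0:
                raise ConfigurationError(
                    f"zone_occupancy[{arm}] must be a 3-simplex, got {occ}")
            if self.manual_intervention_rate[arm] < 0 or self.alarm_rate[arm] < 0:
                raise ConfigurationError("rates must be >= 0")
        if self.phase_minutes <= 0 or self.washout_minutes <= 0:
            raise ConfigurationError("phase and washout durations must be > 0")
        if self.automated_change_rate < 0 or self.rr_mean <= 0:
            raise ConfigurationError("rates must be >= 0 and rr_mean > 0")


_EVENT_MIN_SEP_S = 90.0    # > coalescence window, so events never merge
_EVENT_BUFFER_S = 120.0    # keep events away from phase boundaries
_ALARM_GAP_S = 60.0
_ALARM_BUFFER_S = 30.0


def _patient_rng(config: SyntheticConfig, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(patient_index,)))


def _breath_times(rng: np.random.Generator, total_s: float,
                  rr_mean: float, rr_jitter: float) -> np.ndarray:
    mean = 60.0 / rr_mean
    n_guess = int(total_s / mean * 1.3) + 50
    if rr_jitter <= 0:
        intervals = np.full(n_guess, mean)
    else:
        shape = 1.0 / rr_jitter ** 2
        intervals = rng.gamma(shape, mean / shape, size=n_guess)
    t = np.concatenate(([0.0], np.cumsum(intervals)))
    while t[-1] < total_s:  # pathological jitter draw: extend
        extra = (rng.gamma(shape, mean / shape, size=n_guess)
                 if rr_jitter > 0 else np.full(n_guess, mean))
        t = np.concatenate((t, t[-1] + np.cumsum(extra)))
    return t[t < total_s]


def _separated_times(rng: np.random.Generator, start: float, end: float,
                     n: int, min_sep: float, buffer: float) -> np.ndarray:
    """n time points in [start+buffer, end-buffer] with pairwise gaps >= min_sep."""
    lo, hi = start + buffer, end - buffer
    while n > 0 and (hi - lo) < (n - 1) * min_sep:
        n -= 1  # window cannot host that many events
    if n <= 0:
        return np.empty(0)
    slack = (hi - lo) - (n - 1) * min_sep
    offsets = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + offsets + np.arange(n) * min_sep


def _draw_zone_targets(rng: np.random.Generator, times: np.ndarray,
                       occupancy: Sequence[float],
                       dwell_mean_s: float) -> np.ndarray:
    """Zone index (0/1/2) per breath, constant within each dwell period."""
    n = len(times)
    p = np.asarray(occupancy, float)
    if n == 0:
        return np.empty(0, dtype=int)
    if dwell_mean_s <= 0:
        return rng.choice(3, size=n, p=p)
    span = times[-1] - times[0]
    n_dwell = int(span / dwell_mean_s * 2) + 10
    bounds = times[0] + np.cumsum(rng.exponential(dwell_mean_s, size=n_dwell))
    while bounds[-1] < times[-1]:
        bounds = np.concatenate(
            (bounds, bounds[-1] + np.cumsum(rng.exponential(dwell_mean_s, size=n_dwell))))
    dwell_idx = np.searchsorted(bounds, times, side="right")
    dwell_zone = rng.choice(3, size=int(dwell_idx.max()) + 1, p=p)
    return dwell_zone[dwell_idx]


def generate_patient(
    config: SyntheticConfig, patient_index: int,
) -> tuple[pd.DataFrame, vio.PatientManifest, pd.DataFrame]:
    """One patient's breath log, manifest and per-phase ground truth."""
    rng = _patient_rng(config, patient_index)
    table = zones.load_zone_table(config.zone_table)
    preimage = zones.zone_preimage(table)
    for zone in zones.ZONES:
        if len(preimage[zone]) == 0:
            raise ConfigurationError(
                f"zone {zone!r} has an empty preimage under table "
                f"{table.version!r}; occupancy target unreachable")

    phase_s = config.phase_minutes * 60.0
    washout_s = config.washout_minutes * 60.0
    total_s = 2 * phase_s + washout_s
    first_mode = "automated" if patient_index % 2 == 0 else "conventional"
    second_mode = "conventional" if first_mode == "automated" else "automated"
    patient_id = f"P{patient_index + 1:03d}"

    manifest = vio.PatientManifest(
        patient_id=patient_id, first_mode=first_mode,
        phase1_start=0.0, phase1_end=phase_s,
        phase2_start=phase_s + washout_s, phase2_end=total_s)

    times = _breath_times(rng, total_s, config.rr_mean, config.rr_jitter)
    n = len(times)

    # segment layout: washout behaves like a continuation of phase 1's arm
    windows = [
        (first_mode, 0.0, phase_s, True),
        (first_mode, phase_s, phase_s + washout_s, False),
        (second_mode, phase_s + washout_s, total_s, True),
    ]

    spo2 = np.empty(n)
    peep = np.empty(n)
    fio2 = np.empty(n)
    drawn_zone = np.empty(n, dtype=int)
    for arm, start, end, _ in windows:
        mask = (times >= start) & (times < end)
        z = _draw_zone_targets(rng, times[mask],
                               config.zone_occupancy[arm], config.dwell_mean_s)
        drawn_zone[mask] = z
        for zi, zone in enumerate(zones.ZONES):
            sel = mask.copy()
            sel[mask] = z == zi
            k = int(sel.sum())
            if k:
                picks = preimage[zone][rng.integers(len(preimage[zone]), size=k)]
                spo2[sel], peep[sel], fio2[sel] = picks[:, 0], picks[:, 1], picks[:, 2]

    spo2_missing = np.zeros(n, dtype=bool)
    if config.spo2_missing_rate > 0:
        spo2_missing = rng.random(n) < config.spo2_missing_rate
        spo2[spo2_missing] = np.nan

    # --- arm-dependent columns -------------------------------------------
    mode = np.empty(n, dtype=object)
    controller = np.empty(n, dtype=object)
    for arm, start, end, _ in windows:
        mask = (times >= start) & (times < end)
        if arm == "automated":
            mode[mask] = "automated"
            controller[mask] = "automated"
        else:
            mode[mask] = "conventional_pc"
            controller[mask] = "manual"

    # --- setting-change events -------------------------------------------
    set_fio2 = np.full(n, 35.0)
    set_peep = np.full(n, 6.0)
    hours = phase_s / 3600.0
    gt_events = {arm: {"n_manual": 0, "n_automated": 0} for arm in ARMS}
    event_specs: list[tuple[float, str, str]] = []  # (time, origin, arm)
    for arm, start, end, is_phase in windows:
        if not is_phase:
            continue
        n_manual = rng.poisson(config.manual_intervention_rate[arm] * hours)
        n_auto = (rng.poisson(config.automated_change_rate * hours)
                  if arm == "automated" else 0)
        etimes = _separated_times(rng, start, end, n_manual + n_auto,
                                  _EVENT_MIN_SEP_S, _EVENT_BUFFER_S)
        origins = np.array(["automated"] * len(etimes), dtype=object)
        k_manual = min(n_manual, len(etimes))
        if len(etimes):
            manual_pick = rng.choice(len(etimes), size=k_manual, replace=False)
            origins[manual_pick] = "manual"
        event_specs.extend(
            (t, o, arm) for t, o in zip(etimes.tolist(), origins.tolist()))

    for etime, origin, arm in sorted(event_specs):
        i = int(np.searchsorted(times, etime, side="left"))
        if i <= 0 or i >= n:
            continue
        gt_events[arm][f"n_{'manual' if origin == 'manual' else 'automated'}"] += 1
        if rng.random() < 0.5:  # FiO2 step of +-5 points
            old = set_fio2[i - 1]
            step = 5.0 if rng.random() < 0.5 else -5.0
            new = float(np.clip(old + step, 21.0, 100.0))
            if new == old:
                new = float(np.clip(old - step, 21.0, 100.0))
            set_fio2[i:] = new
        else:  # PEEP step of +-1 cm H2O within the allowed corridor
            old = set_peep[i - 1]
            step = 1.0 if rng.random() < 0.5 else -1.0
            new = float(np.clip(old + step, config.peep_floor, config.peep_ceiling))
            if new == old:
                new = float(np.clip(old - step, config.peep_floor, config.peep_ceiling))
            set_peep[i:] = new
        if origin == "manual" and mode[i] == "automated":
            controller[i] = "manual"  # clinician override breath

    # --- alarm episodes ---------------------------------------------------
    alarm = np.zeros(n, dtype=bool)
    gt_alarms = {arm: {"n_alarms": 0, "alarm_minutes": 0.0} for arm in ARMS}
    for arm, start, end, is_phase in windows:
        if not is_phase:
            continue
        n_alarm = rng.poisson(config.alarm_rate[arm] * hours)
        if n_alarm == 0:
            continue
        durations = rng.exponential(config.alarm_duration_mean_s[arm], size=n_alarm)
        durations = np.clip(durations, 3.0 * 60.0 / config.rr_mean, 300.0)
        min_sep = float(durations.max()) + _ALARM_GAP_S
        starts = _separated_times(rng, start, end, n_alarm, min_sep, _ALARM_BUFFER_S)
        for a_start, dur in zip(starts, durations[: len(starts)]):
            in_ep = (times >= a_start) & (times < a_start + dur)
            if not in_ep.any():
                continue
            alarm |= in_ep
            first = int(np.argmax(in_ep))
            last = n - 1 - int(np.argmax(in_ep[::-1]))
            ep_end = times[last + 1] if last + 1 < n else times[last] + 60.0 / config.rr_mean
            gt_alarms[arm]["n_alarms"] += 1
            gt_alarms[arm]["alarm_minutes"] += (ep_end - times[first]) / 60.0

    frame = pd.DataFrame({
        "time": times, "spo2": spo2, "peep": peep, "fio2": fio2,
        "mode": mode, "controller": controller, "alarm": alarm,
        "set_peep": set_peep, "set_fio2": set_fio2,
    })

    # --- ground truth ------------------------------------------------------
    gt_rows = []
    for arm, start, end, is_phase in windows:
        if not is_phase:
            continue
        mask = (times >= start) & (times < end) & ~spo2_missing
        z = drawn_zone[mask]
        n_classified = len(z)
        row = {"patient_id": patient_id, "phase": arm,
               "n_breaths": int(((times >= start) & (times < end)).sum()),
               "n_classified": n_classified}
        for zi, zone in enumerate(zones.ZONES):
            row[f"pct_{zone}"] = (100.0 * (z == zi).sum() / n_classified
                                  if n_classified else float("nan"))
        row.update(gt_events[arm])
        row.update(gt_alarms[arm])
        gt_rows.append(row)
    ground_truth = pd.DataFrame(gt_rows)

    return frame, manifest, ground_truth


@dataclasses.dataclass
class Cohort:
    """In-memory synthetic cohort: logs, manifests and ground truth."""

    config: SyntheticConfig
    frames: dict[str, pd.DataFrame]
    manifests: list[vio.PatientManifest]
    ground_truth: pd.DataFrame


def generate_cohort(config: SyntheticConfig,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate the full cohort; optionally write it as a CSV directory.

    Patients alternate first mode (even index: automated first), emulating
    1:1 block randomization.  With ``out_dir`` the function writes one
    ``<patient_id>.csv`` log per patient plus ``manifest.csv`` and
    ``ground_truth.csv`` in the exact dialect :mod:`ventzone.io` reads.
    """
    if config.n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    frames: dict[str, pd.DataFrame] = {}
    manifests: list[vio.PatientManifest] = []
    gts = []
    for i in range(config.n_patients):
        frame, manifest, gt = generate_patient(config, i)
        frames[manifest.patient_id] = frame
        manifests.append(manifest)
        gts.append(gt)
    ground_truth = pd.concat(gts, ignore_index=True)
    cohort = Cohort(config=config, frames=frames, manifests=manifests,
                    ground_truth=ground_truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, frame in frames.items():
            vio.write_breath_log(frame, out / f"{pid}.csv")
        vio.write_manifest(manifests, out / "manifest.csv")
        ground_truth.to_csv(out / "ground_truth.csv", index=False,
                            float_format="%.10g")
    return cohort
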