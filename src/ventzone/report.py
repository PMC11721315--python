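"""Pipeline orchestration and paper-shaped output bundles.

``run_analysis`` drives the full chain — read logs, segment phases,
classify breaths, aggregate endpoints, mine events, run the paired
comparison — and writes a reproducible bundle of plain CSV/JSON artifacts:

* ``patient_summaries.csv`` — tidy per-patient endpoint values;
* ``zone_comparison.csv`` / ``event_comparison.csv`` — the occupancy and
  intervention/alarm comparison tables (median [IQR], mean (SD), paired p);
* ``ecdf_<variable>.csv`` — cumulative-distribution data of the per-patient
  median SpO2 / PEEP / FiO2 per arm;
* ``zone_bars.csv`` — per-arm mean zone percentages for the three views;
* ``run_log.json`` — package version, zone-table version, thresholds and a
  config hash, so outputs carry full provenance;
* ``errors.csv`` — per-patient failures (the bundle still covers the rest).

Plot *data* files are the first-class outputs; rendering is left to the
caller.  Every CSV starts with a ``#`` provenance comment line (read them
back with ``comment="#"``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import aggregation, events, stats, zones
from . import io as vio
from .errors import ValidationError, VentzoneError


def ecdf_points(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Empirical CDF as (value, cumulative_fraction) rows, one per distinct value.

    Fractions increase to exactly 1.0 at the largest value.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValidationError("ecdf_points needs at least one value")
    distinct, counts = np.unique(v, return_counts=True)
    frac = np.cumsum(counts) / len(v)
    return np.column_stack((distinct, frac))


def zone_bar_data(summaries: Sequence[aggregation.PatientSummary]) -> pd.DataFrame:
    """Per-arm mean zone percentages for all three classification views.

    One row per arm x view x zone; within each arm x view the three means
    sum to ~100 over patients with classified breaths.
    """
    if not summaries:
        raise ValidationError("zone_bar_data needs at least one patient")
    rows = []
    for arm in ("automated", "conventional"):
        for view in aggregation.VIEWS:
            for zone in zones.ZONES:
                vals = np.array([s.phases[arm].pct_breaths[view][zone]
                                 for s in summaries], float)
                rows.append({
                    "arm": arm, "view": view, "zone": zone,
                    "mean_pct": float(np.nanmean(vals)) if np.isfinite(vals).any()
                    else float("nan"),
                    "n_patients": int(np.isfinite(vals).sum()),
                })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class AnalysisConfig:
    """Everything one analysis run depends on."""

    input_dir: str
    manifest_path: str | None = None  # default: <input_dir>/manifest.csv
    zone_table: str = "default_v1"
    schema: dict | None = None        # column mapping for vendor CSVs
    peep_threshold: float = events.DEFAULT_PEEP_THRESHOLD
    fio2_threshold: float = events.DEFAULT_FIO2_THRESHOLD
    coalescence_window_s: float = events.DEFAULT_COALESCENCE_WINDOW_S
    duration_cap_s: float = aggregation.DEFAULT_DURATION_CAP_S
    alpha: float = 0.05
    out_dir: str = "results"

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")  # where the bundle lands must not change its content
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(frame: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {provenance}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def run_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Run the whole pipeline and write the output bundle.

    Patients whose log fails to parse or validate are recorded in
    ``errors.csv``; the bundle is produced for the remaining patients.
    Identical inputs and config produce byte-identical outputs.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(config.manifest_path or in_dir / "manifest.csv")

    table = zones.load_zone_table(config.zone_table)
    manifests = vio.read_manifest(manifest_path)
    provenance = (f"ventzone {__version__} zone_table={table.version} "
                  f"config={config.config_hash()}")

    summaries: list[aggregation.PatientSummary] = []
    count_frames: list[pd.DataFrame] = []
    median_rows: list[dict] = []
    error_rows: list[dict] = []

    for manifest in manifests:
        pid = manifest.patient_id
        try:
            frame, _report = vio.read_breath_log(in_dir / f"{pid}.csv",
                                                 schema=config.schema)
            segments, _ = aggregation.segment_phases(frame, manifest)
            summaries.append(aggregation.summarize_patient(
                segments, table, cap_s=config.duration_cap_s))
            evs = events.detect_setting_changes(
                frame, patient_id=pid,
                peep_threshold=config.peep_threshold,
                fio2_threshold=config.fio2_threshold,
                window_s=config.coalescence_window_s)
            eps = events.detect_alarm_episodes(frame, patient_id=pid,
                                               cap_s=config.duration_cap_s)
            count_frames.append(events.count_events_per_phase(evs, eps, manifest))
            for seg in segments:
                if seg.phase_label == "washout" or seg.frame.empty:
                    continue
                median_rows.append({
                    "patient_id": pid, "arm": seg.phase_label,
                    "spo2": float(seg.frame["spo2"].median()),
                    "peep": float(seg.frame["peep"].median()),
                    "fio2": float(seg.frame["fio2"].median()),
                })
        except VentzoneError as exc:
            error_rows.append({"patient_id": pid, "stage": type(exc).__name__,
                               "error": str(exc)})

    outputs: dict[str, Path] = {}

    summary_frame = aggregation.summaries_to_frame(summaries)
    outputs["patient_summaries"] = out_dir / "patient_summaries.csv"
    _write_csv(summary_frame, outputs["patient_summaries"], provenance)

    if count_frames:
        counts = pd.concat(count_frames, ignore_index=True)
    else:
        counts = pd.DataFrame(columns=["patient_id", "phase", "n_manual",
                                       "n_automated", "n_alarms", "alarm_minutes"])
    outputs["event_counts"] = out_dir / "event_counts.csv"
    _write_csv(counts, outputs["event_counts"], provenance)

    if len(summaries) >= 2:
        zone_cmp, event_cmp = stats.compare_all_endpoints(
            summaries, counts, alpha=config.alpha)
        outputs["zone_comparison"] = out_dir / "zone_comparison.csv"
        _write_csv(zone_cmp, outputs["zone_comparison"], provenance)
        outputs["event_comparison"] = out_dir / "event_comparison.csv"
        _write_csv(event_cmp, outputs["event_comparison"], provenance)

    medians = pd.DataFrame(median_rows)
    for variable in ("spo2", "peep", "fio2"):
        rows = []
        for arm in ("automated", "conventional"):
            if len(medians) and (medians["arm"] == arm).any():
                vals = medians.loc[medians["arm"] == arm, variable].dropna()
                if len(vals):
                    for value, frac in ecdf_points(vals.to_numpy()):
                        rows.append({"arm": arm, "value": value,
                                     "cumulative_fraction": frac})
        outputs[f"ecdf_{variable}"] = out_dir / f"ecdf_{variable}.csv"
        _write_csv(pd.DataFrame(rows, columns=["arm", "value", "cumulative_fraction"]),
                   outputs[f"ecdf_{variable}"], provenance)

    if summaries:
        outputs["zone_bars"] = out_dir / "zone_bars.csv"
        _write_csv(zone_bar_data(summaries), outputs["zone_bars"], provenance)

    outputs["errors"] = out_dir / "errors.csv"
    _write_csv(pd.DataFrame(error_rows, columns=["patient_id", "stage", "error"]),
               outputs["errors"], provenance)

    run_log = {
        "package_version": __version__,
        "zone_table_version": table.version,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "n_patients_analyzed": len(summaries),
        "n_patients_failed": len(error_rows),
    }
    outputs["run_log"] = out_dir / "run_log.json"
    with open(outputs["run_log"], "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outputs
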