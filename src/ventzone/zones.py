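"""Per-breath oxygenation-zone classification.

Every breath is scored in three steps:

1. the SpO2 value is looked up in a band table (optimal / acceptable /
   critical; missing SpO2 -> unclassified);
2. the (PEEP, FiO2) pair is scored against a titration grid adapted from the
   ARDS Network lower-PEEP/higher-FiO2 table: inside the allowed PEEP range
   for the breath's FiO2 bin -> optimal; within ``pf_tolerance_steps`` grid
   moves of an optimal cell -> acceptable; farther -> critical.  A grid move
   is one FiO2-bin step or one 1-cm H2O PEEP step;
3. the two zone values are combined, by default taking the worse of the two
   on the order optimal < acceptable < critical.

All cutoffs live in a :class:`ZoneTable` loaded from a versioned YAML
document so an analysis can be reproduced against a named table.
"""

from __future__ import annotations

import dataclasses
import functools
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

OPTIMAL = "optimal"
ACCEPTABLE = "acceptable"
CRITICAL = "critical"
UNCLASSIFIED = "unclassified"

#: the three real zones, ordered from best to worst
ZONES = (OPTIMAL, ACCEPTABLE, CRITICAL)

_SEVERITY = {OPTIMAL: 0, ACCEPTABLE: 1, CRITICAL: 2}


@dataclasses.dataclass(frozen=True)
class SpO2Band:
    lower: float  # inclusive
    upper: float  # exclusive, except the final band which is closed
    label: str


@dataclasses.dataclass(frozen=True)
class PFRow:
    """One FiO2 bin of the PEEP/FiO2 grid with its allowed PEEP range."""
    fio2_lower: float  # exclusive (first row: inclusive)
    fio2_upper: float  # inclusive
    peep_lower: float
    peep_upper: float


@dataclasses.dataclass(frozen=True)
class ZoneTable:
    """A versioned, fully configurable oxygenation zone definition."""

    version: str
    spo2_bands: tuple[SpO2Band, ...]
    pf_grid: tuple[PFRow, ...]
    pf_tolerance_steps: int = 1
    combination_rule: str = "worst_of"

    def __post_init__(self) -> None:
        bands = sorted(self.spo2_bands, key=lambda b: b.lower)
        object.__setattr__(self, "spo2_bands", tuple(bands))
        if not bands or bands[0].lower != 50.0 or bands[-1].upper != 100.0:
            raise ConfigurationError("spo2_bands must cover [50, 100]")
        for a, b in zip(bands, bands[1:]):
            if a.upper != b.lower:
                raise ConfigurationError(
                    f"spo2_bands gap/overlap between {a.upper} and {b.lower}")
        for band in bands:
            if band.label not in ZONES:
                raise ConfigurationError(f"unknown SpO2 band label {band.label!r}")
        grid = sorted(self.pf_grid, key=lambda r: r.fio2_lower)
        object.__setattr__(self, "pf_grid", tuple(grid))
        if not grid or grid[0].fio2_lower != 21.0 or grid[-1].fio2_upper != 100.0:
            raise ConfigurationError("pf_grid FiO2 bins must cover [21, 100]")
        for a, b in zip(grid, grid[1:]):
            if a.fio2_upper != b.fio2_lower:
                raise ConfigurationError(
                    f"pf_grid bins gap/overlap at FiO2 {a.fio2_upper}")
        for row in grid:
            if row.peep_lower > row.peep_upper:
                raise ConfigurationError("pf_grid PEEP range inverted")
        if self.pf_tolerance_steps < 0:
            raise ConfigurationError("pf_tolerance_steps must be >= 0")
        if self.combination_rule not in ("worst_of", "spo2_priority"):
            raise ConfigurationError(
                f"unknown combination_rule {self.combination_rule!r}")

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "ZoneTable":
        try:
            bands = tuple(
                SpO2Band(float(b["lower"]), float(b["upper"]), str(b["label"]))
                for b in doc["spo2_bands"])
            grid = tuple(
                PFRow(float(r["fio2_lower"]), float(r["fio2_upper"]),
                      float(r["peep_lower"]), float(r["peep_upper"]))
                for r in doc["pf_grid"])
            return cls(
                version=str(doc.get("version", "unversioned")),
                spo2_bands=bands,
                pf_grid=grid,
                pf_tolerance_steps=int(doc.get("pf_tolerance_steps", 1)),
                combination_rule=str(doc.get("combination_rule", "worst_of")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed zone-table document: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ZoneTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "spo2_bands": [dataclasses.asdict(b) for b in self.spo2_bands],
            "pf_grid": [dataclasses.asdict(r) for r in self.pf_grid],
            "pf_tolerance_steps": self.pf_tolerance_steps,
            "combination_rule": self.combination_rule,
        }


@functools.lru_cache(maxsize=8)
def load_zone_table(name_or_path: str = "default_v1") -> ZoneTable:
    """Load a shipped named table (e.g. ``default_v1``) or a YAML file path."""
    candidate = Path(name_or_path)
    if candidate.suffix in (".yaml", ".yml") and candidate.exists():
        return ZoneTable.from_yaml(candidate)
    ref = resources.files("ventzone.tables").joinpath(f"{name_or_path}.yaml")
    if not ref.is_file():
        raise ConfigurationError(f"no shipped zone table named {name_or_path!r}")
    with ref.open("r", encoding="utf-8") as fh:
        return ZoneTable.from_dict(yaml.safe_load(fh))


# -- SpO2 step -------------------------------------------------------------

def classify_spo2(spo2: float | None, table: ZoneTable) -> str:
    """Band lookup for one SpO2 value; missing -> unclassified."""
    if spo2 is None or (isinstance(spo2, float) and np.isnan(spo2)):
        return UNCLASSIFIED
    if spo2 < 50.0 or spo2 > 100.0:
        raise ValidationError(f"SpO2 {spo2} outside [50, 100] (sensor artifact?)")
    return classify_spo2_array(np.asarray([spo2], float), table)[0]


def classify_spo2_array(spo2: np.ndarray, table: ZoneTable) -> np.ndarray:
    """Vectorised SpO2 band lookup; NaN -> unclassified."""
    spo2 = np.asarray(spo2, float)
    present = ~np.isnan(spo2)
    if present.any():
        vals = spo2[present]
        if (vals < 50.0).any() or (vals > 100.0).any():
            bad = vals[(vals < 50.0) | (vals > 100.0)][0]
            raise ValidationError(f"SpO2 {bad} outside [50, 100] (sensor artifact?)")
    uppers = np.array([b.upper for b in table.spo2_bands])
    labels = np.array([b.label for b in table.spo2_bands], dtype=object)
    out = np.full(spo2.shape, UNCLASSIFIED, dtype=object)
    # upper edge is exclusive except at 100, hence side="right" + clip
    idx = np.searchsorted(uppers, spo2[present], side="right")
    idx = np.minimum(idx, len(uppers) - 1)
    out[present] = labels[idx]
    return out


# -- PEEP/FiO2 step --------------------------------------------------------

def _fio2_row_index(fio2: np.ndarray, table: ZoneTable) -> np.ndarray:
    lowers = np.array([r.fio2_lower for r in table.pf_grid])
    # bins are (lower, upper]; searchsorted on lowers with side="left" puts a
    # value equal to a bin's lower edge in the bin below, as required
    idx = np.searchsorted(lowers, fio2, side="left") - 1
    return np.clip(idx, 0, len(table.pf_grid) - 1)


def pf_grid_distance(peep: float, fio2: float, table: ZoneTable) -> int:
    """Minimum number of grid steps from (peep, fio2) to an optimal cell.

    One step is a single FiO2-bin move or a single 1-cm H2O PEEP move; PEEP
    is quantized to the nearest integer cm H2O before counting steps.
    Computed by brute-force minimisation over all grid rows.
    """
    if fio2 < 21.0 or fio2 > 100.0:
        raise ValidationError(f"FiO2 {fio2} outside [21, 100]")
    r = int(_fio2_row_index(np.asarray([fio2], float), table)[0])
    q = float(np.round(peep))
    best = None
    for i, row in enumerate(table.pf_grid):
        peep_steps = max(0.0, np.ceil(row.peep_lower - q), np.ceil(q - row.peep_upper))
        d = abs(i - r) + int(peep_steps)
        best = d if best is None else min(best, d)
    return int(best)


def classify_peep_fio2(peep: float, fio2: float, table: ZoneTable) -> str:
    """Score one (PEEP, FiO2) pair against the titration grid."""
    return classify_pf_array(np.asarray([peep], float),
                             np.asarray([fio2], float), table)[0]


def classify_pf_array(peep: np.ndarray, fio2: np.ndarray,
                      table: ZoneTable) -> np.ndarray:
    """Vectorised PEEP/FiO2 scoring; NaN in either input -> unclassified."""
    peep = np.asarray(peep, float)
    fio2 = np.asarray(fio2, float)
    present = ~(np.isnan(peep) | np.isnan(fio2))
    if present.any():
        f = fio2[present]
        if (f < 21.0).any() or (f > 100.0).any():
            bad = f[(f < 21.0) | (f > 100.0)][0]
            raise ValidationError(f"FiO2 {bad} outside [21, 100]")
        p = peep[present]
        if (p < 0.0).any() or (p > 30.0).any():
            bad = p[(p < 0.0) | (p > 30.0)][0]
            raise ValidationError(f"PEEP {bad} outside [0, 30]")

    out = np.full(peep.shape, UNCLASSIFIED, dtype=object)
    if not present.any():
        return out

    rows = _fio2_row_index(fio2[present], table)
    lo = np.array([r.peep_lower for r in table.pf_grid])
    hi = np.array([r.peep_upper for r in table.pf_grid])
    p = peep[present]
    in_range = (p >= lo[rows]) & (p <= hi[rows])

    # distance to the nearest optimal cell, minimised over all rows
    q = np.round(p)
    n_rows = len(table.pf_grid)
    row_idx = np.arange(n_rows)
    # (breath, row) matrices; small because grids have a handful of rows
    fio2_steps = np.abs(rows[:, None] - row_idx[None, :])
    peep_steps = np.maximum(0.0, np.maximum(np.ceil(lo[None, :] - q[:, None]),
                                            np.ceil(q[:, None] - hi[None, :])))
    dist = (fio2_steps + peep_steps).min(axis=1)

    labels = np.where(in_range, OPTIMAL,
                      np.where(dist <= table.pf_tolerance_steps, ACCEPTABLE, CRITICAL))
    out[present] = labels
    return out


# -- combination -----------------------------------------------------------

def combine_zones(spo2_zone: str, pf_zone: str,
                  rule: str = "worst_of") -> str:
    """Combine the SpO2 and PEEP/FiO2 zones into the breath zone."""
    if spo2_zone == UNCLASSIFIED or pf_zone == UNCLASSIFIED:
        return UNCLASSIFIED
    if rule == "worst_of":
        return spo2_zone if _SEVERITY[spo2_zone] >= _SEVERITY[pf_zone] else pf_zone
    if rule == "spo2_priority":
        return spo2_zone
    raise ConfigurationError(f"unknown combination_rule {rule!r}")


def classify_breaths(frame: pd.DataFrame, table: ZoneTable) -> np.ndarray:
    """Combined zone label for every breath of a canonical frame."""
    return classify_views(frame, table)["combined"].to_numpy()


def classify_views(frame: pd.DataFrame, table: ZoneTable) -> pd.DataFrame:
    """All three classification views, row-parallel to ``frame``.

    Returns a frame with columns ``spo2_zone``, ``pf_zone`` and ``combined``.
    """
    spo2_zone = classify_spo2_array(frame["spo2"].to_numpy(float), table)
    pf_zone = classify_pf_array(frame["peep"].to_numpy(float),
                                frame["fio2"].to_numpy(float), table)
    unclass = (spo2_zone == UNCLASSIFIED) | (pf_zone == UNCLASSIFIED)
    sev_map = {**_SEVERITY, UNCLASSIFIED: np.nan}
    if table.combination_rule == "worst_of":
        sev_s = np.vectorize(sev_map.get, otypes=[float])(spo2_zone)
        sev_p = np.vectorize(sev_map.get, otypes=[float])(pf_zone)
        worst = np.where(np.fmax(sev_s, sev_p) == sev_s, spo2_zone, pf_zone)
        combined = np.where(unclass, UNCLASSIFIED, worst)
    else:  # spo2_priority
        combined = np.where(unclass, UNCLASSIFIED, spo2_zone)
    return pd.DataFrame({
        "spo2_zone": spo2_zone, "pf_zone": pf_zone, "combined": combined,
    }, index=frame.index)


def zone_preimage(table: ZoneTable,
                  spo2_grid: Iterable[int] = range(70, 101),
                  peep_grid: Iterable[int] = range(0, 25),
                  fio2_grid: Iterable[int] = range(21, 101)) -> dict[str, np.ndarray]:
    """Brute-force sweep: integer (spo2, peep, fio2) triples per combined zone.

    Used by the synthetic generator to draw values whose classification is
    known by construction.
    """
    s, p, f = np.meshgrid(np.asarray(list(spo2_grid), float),
                          np.asarray(list(peep_grid), float),
                          np.asarray(list(fio2_grid), float), indexing="ij")
    frame = pd.DataFrame({"spo2": s.ravel(), "peep": p.ravel(), "fio2": f.ravel()})
    labels = classify_views(frame, table)["combined"].to_numpy()
    triples = frame.to_numpy()
    return {zone: triples[labels == zone] for zone in ZONES}
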