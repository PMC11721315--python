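import itertools

import numpy as np
import pandas as pd
import pytest

from ventzone import zones
from ventzone.errors import ConfigurationError, ValidationError

from conftest import make_frame

# --------------------------------------------------------------------------
# Independent per-breath re-classification oracle for the shipped default
# table, coded from the documented cutoffs without touching package logic.
# --------------------------------------------------------------------------

_ORACLE_PF_ROWS = [  # (fio2_low, fio2_high, peep_low, peep_high)
    (21, 30, 5, 5), (30, 40, 5, 8), (40, 50, 8, 10), (50, 60, 10, 10),
    (60, 70, 10, 14), (70, 80, 14, 14), (80, 90, 14, 18), (90, 100, 18, 24),
]


def oracle_spo2(s):
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return "unclassified"
    if s < 90:
        return "critical"
    if s < 93:
        return "acceptable"
    if s < 98:
        return "optimal"
    return "acceptable"


def _oracle_row(fio2):
    for i, (lo, hi, _, _) in enumerate(_ORACLE_PF_ROWS):
        if (fio2 <= hi) and (fio2 > lo or (i == 0 and fio2 >= lo)):
            return i
    raise AssertionError(fio2)


def oracle_pf_distance(peep, fio2):
    """Breadth-first search over (row, integer PEEP) states; one move is one
    FiO2-row step or one 1-cmH2O PEEP step."""
    start = (_oracle_row(fio2), int(round(peep)))
    seen = {start}
    frontier = [start]
    dist = 0
    while True:
        for row, q in frontier:
            lo, hi = _ORACLE_PF_ROWS[row][2:]
            if lo <= q <= hi:
                return dist
        nxt = []
        for row, q in frontier:
            for cand in ((row - 1, q), (row + 1, q), (row, q - 1), (row, q + 1)):
                if 0 <= cand[0] < len(_ORACLE_PF_ROWS) and cand not in seen:
                    seen.add(cand)
                    nxt.append(cand)
        frontier = nxt
        dist += 1


def oracle_pf(peep, fio2):
    if np.isnan(peep) or np.isnan(fio2):
        return "unclassified"
    lo, hi = _ORACLE_PF_ROWS[_oracle_row(fio2)][2:]
    if lo <= peep <= hi:
        return "optimal"
    return "acceptable" if oracle_pf_distance(peep, fio2) <= 1 else "critical"


def oracle_combined(s, p, f):
    zs, zp = oracle_spo2(s), oracle_pf(p, f)
    if "unclassified" in (zs, zp):
        return "unclassified"
    order = {"optimal": 0, "acceptable": 1, "critical": 2}
    return zs if order[zs] >= order[zp] else zp


# --------------------------------------------------------------------------


class TestClassifySpo2:
    @pytest.mark.parametrize("spo2, expected", [
        (94, "optimal"), (88, "critical"), (90, "acceptable"),
        (92.9, "acceptable"), (93, "optimal"), (97.9, "optimal"),
        (98, "acceptable"), (100, "acceptable"), (50, "critical"),
    ])
    def test_band_lookup(self, default_table, spo2, expected):
        assert zones.classify_spo2(spo2, default_table) == expected

    def test_missing_is_unclassified(self, default_table):
        assert zones.classify_spo2(float("nan"), default_table) == "unclassified"
        assert zones.classify_spo2(None, default_table) == "unclassified"

    def test_sensor_artifact_rejected(self, default_table):
        with pytest.raises(ValidationError):
            zones.classify_spo2(45.0, default_table)


class TestClassifyPeepFio2:
    def test_exact_grid_cell_is_optimal(self, default_table):
        assert zones.classify_peep_fio2(5, 30, default_table) == "optimal"

    def test_low_peep_at_full_oxygen_is_critical(self, default_table):
        # far from the allowed PEEP range at FiO2 100; oracle confirms
        assert oracle_pf_distance(5, 100) > default_table.pf_tolerance_steps
        assert zones.classify_peep_fio2(5, 100, default_table) == "critical"

    def test_near_miss_matches_distance_oracle(self, default_table):
        label = zones.classify_peep_fio2(8, 40, default_table)
        assert label == oracle_pf(8, 40)
        assert label in ("optimal", "acceptable")

    def test_distance_agrees_with_bfs_oracle_on_grid(self, default_table):
        rng = np.random.default_rng(5)
        for _ in range(300):
            peep = int(rng.integers(0, 25))
            fio2 = int(rng.integers(21, 101))
            assert (zones.pf_grid_distance(peep, fio2, default_table)
                    == oracle_pf_distance(peep, fio2)), (peep, fio2)

    def test_fio2_below_range_rejected(self, default_table):
        with pytest.raises(ValidationError):
            zones.classify_peep_fio2(5, 20, default_table)


class TestCombineZones:
    @pytest.mark.parametrize("a, b, expected", [
        ("optimal", "optimal", "optimal"),
        ("optimal", "critical", "critical"),
        ("acceptable", "optimal", "acceptable"),
        ("unclassified", "optimal", "unclassified"),
        ("critical", "unclassified", "unclassified"),
    ])
    def test_worst_of(self, a, b, expected):
        assert zones.combine_zones(a, b, "worst_of") == expected

    def test_worst_of_monotone_in_both_arguments(self):
        order = {"optimal": 0, "acceptable": 1, "critical": 2}
        for a, b in itertools.product(zones.ZONES, repeat=2):
            combined = order[zones.combine_zones(a, b)]
            for worse in zones.ZONES:
                if order[worse] >= order[a]:
                    assert order[zones.combine_zones(worse, b)] >= combined
                if order[worse] >= order[b]:
                    assert order[zones.combine_zones(a, worse)] >= combined

    def test_spo2_priority_returns_spo2_zone(self):
        assert zones.combine_zones("optimal", "critical", "spo2_priority") == "optimal"


class TestClassifyBreaths:
    def test_empty_log_gives_empty_labels(self, default_table):
        assert len(zones.classify_breaths(make_frame([]), default_table)) == 0

    def test_matches_per_breath_oracle(self, default_table):
        rng = np.random.default_rng(42)
        n = 1000
        spo2 = rng.uniform(50, 100, size=n).round(1)
        spo2[rng.random(n) < 0.05] = np.nan
        frame = make_frame(np.arange(n, dtype=float) * 3.0, spo2=spo2,
                           peep=rng.integers(0, 25, size=n).astype(float),
                           fio2=rng.integers(21, 101, size=n).astype(float))
        labels = zones.classify_breaths(frame, default_table)
        expected = [oracle_combined(s, p, f) for s, p, f in
                    zip(frame["spo2"], frame["peep"], frame["fio2"])]
        assert labels.tolist() == expected

    def test_all_spo2_missing_gives_all_unclassified(self, default_table):
        frame = make_frame([0.0, 3.0, 6.0], spo2=np.nan)
        assert (zones.classify_breaths(frame, default_table) == "unclassified").all()

    def test_partition_completeness_on_integer_grid(self, default_table):
        s, p, f = np.meshgrid(np.arange(70, 101), np.arange(0, 25),
                              np.arange(21, 101), indexing="ij")
        frame = pd.DataFrame({"spo2": s.ravel().astype(float),
                              "peep": p.ravel().astype(float),
                              "fio2": f.ravel().astype(float)})
        labels = zones.classify_views(frame, default_table)["combined"]
        assert set(labels.unique()) <= set(zones.ZONES)
        assert not labels.isna().any()

    def test_degenerate_table_maps_everything_to_optimal(self):
        table = zones.ZoneTable(
            version="degenerate",
            spo2_bands=(zones.SpO2Band(50, 100, "optimal"),),
            pf_grid=(zones.PFRow(21, 100, 0, 30),),
            pf_tolerance_steps=0)
        rng = np.random.default_rng(0)
        frame = make_frame(np.arange(200.0),
                           spo2=rng.uniform(50, 100, 200),
                           peep=rng.uniform(0, 24, 200),
                           fio2=rng.uniform(21, 100, 200))
        assert (zones.classify_breaths(frame, table) == "optimal").all()


class TestZoneTableConfig:
    def test_gap_in_spo2_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            zones.ZoneTable(version="bad",
                            spo2_bands=(zones.SpO2Band(50, 90, "critical"),
                                        zones.SpO2Band(92, 100, "optimal")),
                            pf_grid=(zones.PFRow(21, 100, 0, 30),))

    def test_fio2_bins_must_cover_range(self):
        with pytest.raises(ConfigurationError):
            zones.ZoneTable(version="bad",
                            spo2_bands=(zones.SpO2Band(50, 100, "optimal"),),
                            pf_grid=(zones.PFRow(30, 100, 0, 30),))

    def test_yaml_round_trip(self, default_table, tmp_path):
        import yaml
        path = tmp_path / "table.yaml"
        path.write_text(yaml.safe_dump(default_table.to_dict()))
        assert zones.ZoneTable.from_yaml(path) == default_table

    def test_unknown_named_table_rejected(self):
        with pytest.raises(ConfigurationError):
            zones.load_zone_table("no_such_table")

    def test_preimage_labels_are_self_consistent(self, default_table):
        pre = zones.zone_preimage(default_table)
        for zone in zones.ZONES:
            assert len(pre[zone]) > 0
            sample = pre[zone][:: max(1, len(pre[zone]) // 50)]
            frame = pd.DataFrame(sample, columns=["spo2", "peep", "fio2"])
            assert (zones.classify_views(frame, default_table)["combined"]
                    == zone).all()
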