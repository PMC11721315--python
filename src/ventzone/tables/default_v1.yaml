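# Default oxygenation zone table, version "default_v1".
#
# This table is a documented reconstruction assembled from the literature the
# method builds on, NOT a verbatim clinical appendix: SpO2 bands follow common
# ICU target-range recommendations, and the PEEP/FiO2 grid is the ARDS Network
# lower-PEEP/higher-FiO2 titration table expressed as FiO2 bins with allowed
# PEEP ranges.  Every analysis records the version string of the table it used.
version: default_v1

# SpO2 bands: lower-inclusive, upper-exclusive, except the last band which is
# closed at 100.  Bands must tile [50, 100] with no gaps or overlaps.
spo2_bands:
  - {lower: 50, upper: 90, label: critical}
  - {lower: 90, upper: 93, label: acceptable}
  - {lower: 93, upper: 98, label: optimal}
  - {lower: 98, upper: 100, label: acceptable}

# PEEP/FiO2 grid: ascending FiO2 bins (lower-exclusive, upper-inclusive; the
# first bin also includes its lower edge 21) with the allowed PEEP range in
# cm H2O.  A (PEEP, FiO2) pair inside its bin's PEEP range is optimal.
pf_grid:
  - {fio2_lower: 21, fio2_upper: 30, peep_lower: 5, peep_upper: 5}
  - {fio2_lower: 30, fio2_upper: 40, peep_lower: 5, peep_upper: 8}
  - {fio2_lower: 40, fio2_upper: 50, peep_lower: 8, peep_upper: 10}
  - {fio2_lower: 50, fio2_upper: 60, peep_lower: 10, peep_upper: 10}
  - {fio2_lower: 60, fio2_upper: 70, peep_lower: 10, peep_upper: 14}
  - {fio2_lower: 70, fio2_upper: 80, peep_lower: 14, peep_upper: 14}
  - {fio2_lower: 80, fio2_upper: 90, peep_lower: 14, peep_upper: 18}
  - {fio2_lower: 90, fio2_upper: 100, peep_lower: 18, peep_upper: 24}

# Pairs within this many grid steps (one FiO2-bin move or one 1-cmH2O PEEP
# move each) of an optimal cell are 'acceptable'; anything farther 'critical'.
pf_tolerance_steps: 1

# How the SpO2 zone and the PEEP/FiO2 zone combine into the breath zone.
combination_rule: worst_of
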