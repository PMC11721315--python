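# Methods

## The measurement problem

During invasive ventilation, oxygenation is steered with two ventilator
settings — FiO₂ (inspired-oxygen fraction, 21–100 %) and PEEP (positive
end-expiratory pressure, cm H₂O) — against a continuously measured SpO₂.
A breath is "well oxygenated" not when SpO₂ alone is in range but when the
*combination* of achieved saturation and the settings used to achieve it is
sensible: SpO₂ 96 % at FiO₂ 100 % with PEEP 5 is not the same quality of
care as SpO₂ 96 % at FiO₂ 30 %. The package therefore scores every breath
on two axes and combines them, then aggregates to per-patient, per-phase
endpoints suitable for a paired two-period crossover comparison between an
automated (closed-loop) and a conventional ventilation arm.

## Zone model

**SpO₂ bands.** The default table maps SpO₂ < 90 % to *critical*,
90–92 % to *acceptable*, 93–97 % to *optimal* and 98–100 % to *acceptable*
(hyperoxia-leaning saturation under supplemental oxygen is not optimal).
Bands are stored lower-inclusive / upper-exclusive with the last band
closed at 100 so that they tile the continuous range [50, 100] without
gaps; a missing SpO₂ makes the breath *unclassified*; a value outside
[50, 100] is rejected as a sensor artifact.

**PEEP/FiO₂ grid.** FiO₂ is binned into the eight steps of the ARDS
Network lower-PEEP/higher-FiO₂ titration table, each bin carrying its
allowed PEEP range (21–30 % → 5; 30–40 % → 5–8; 40–50 % → 8–10; 50–60 % →
10; 60–70 % → 10–14; 70–80 % → 14; 80–90 % → 14–18; 90–100 % → 18–24
cm H₂O). A pair inside its bin's range is *optimal*. Otherwise the
grid-step distance to the nearest optimal cell is computed — one step is
one FiO₂-bin move or one 1-cm H₂O PEEP move — by brute-force minimisation
over all bins; distance ≤ `pf_tolerance_steps` (default 1) is *acceptable*,
farther is *critical*. PEEP is quantized to the nearest integer cm H₂O for
the distance computation (ventilators set PEEP in whole or half steps, and
a ±1-move walk from a fractional start could otherwise never land inside a
single-valued range like "PEEP 5").

**Combination.** The default `worst_of` rule takes the worse of the two
zones on the order optimal < acceptable < critical; `spo2_priority`
(saturation dominates, settings ignored) is available for sensitivity
analyses. Either input unclassified makes the breath unclassified.

**Provenance.** The shipped table is an explicit reconstruction from the
recommendations the method builds on, *not* a transcription of any single
study's appendix; it is versioned (`default_v1`), ships as YAML package
data, can be replaced wholesale by config, and every output file records
the version used.

## Endpoints

Percentage of breaths in a zone is `100 · n_zone / n_classified` per
patient-phase and view (combined, SpO₂-only, PEEP/FiO₂-only). Unclassified
breaths are excluded from denominators — the three zone percentages then
sum to 100 exactly — and the unclassified fraction is carried alongside.
A phase with zero classified breaths yields a missing value, never 0.

Percentage of time weights each breath by its duration: the interval to
the next breath, capped at 15 s so monitoring dropouts cannot dominate a
phase, with the final breath inheriting the segment's median duration
(it has no successor). With equal durations the time and breath fractions
coincide. Single-breath segments give a missing value with a warning.

Phase windows come from a per-patient manifest and are half-open
`[start, end)`; a record exactly at a phase end belongs to the next window.
Washout breaths are segmented but excluded from every endpoint.

## Event mining

A raw setting change is a breath-to-breath difference in *set* PEEP or
FiO₂ of at least 0.5 cm H₂O or 1 percentage point respectively (smaller
deltas are telemetry jitter). Consecutive same-parameter, same-direction
raw changes closer than 60 s coalesce into one intervention spanning the
first old value to the last new value; a direction reversal or a longer
pause starts a new one. The origin is the automation-controller status at
the change breath: `manual` or `frozen` → manual (a frozen controller
implies clinician override), `automated` → automated. PEEP and FiO₂
changes at the same moment count as two interventions (the two knobs are
clinically distinct actions). All thresholds are configurable and exposed
as CLI flags.

Alarm episodes are maximal runs of the oxygenation-alarm flag, with runs
separated by at most one quiet breath merged (a single dropped flag inside
an alarm is noise). Duration runs from the first alarmed breath to the end
of the last one. Episodes straddling a phase boundary are split there and
their duration apportioned, so cumulative alarm minutes are conserved
across windows.

## Statistics

Endpoints are compared with a two-sided Wilcoxon signed-rank test on the
within-patient differences (automated − conventional). Zeros are discarded
before ranking by default (classic Wilcoxon; Pratt's zero-rank method is
an option), and tied absolute differences receive mid-ranks. For at most
20 informative pairs the p-value is exact: the null distribution of the
positive-rank sum W⁺ over all 2^m sign assignments is built by convolution
over the doubled (hence integer) ranks, which is arithmetically identical
to full enumeration; beyond that a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used. Descriptives are median
[IQR] and mean (SD), with linear-interpolation quartiles and an n−1
standard deviation. The significance level 0.05 only flags rows; nothing
is filtered, and no multiple-testing correction is applied — every
endpoint's raw p is reported, and readers should treat the many secondary
p-values accordingly.

Two built-in Monte-Carlo harnesses calibrate the test as used here: under
the null (both arms from one distribution, 50 pairs, 1,000 replicates) the
rejection rate at α = 0.05 stays within [0.03, 0.07]; a 2-event shift in
paired Poisson intervention counts at 50 pairs is detected in well over
80 % of replicates.

## Synthetic generator

The generator reproduces the statistical structure of a crossover
ventilator log, not respiratory physiology — its purpose is to give every
pipeline stage a ground truth. Defaults are the study-scale conditions the
package targets: 53 patients, two 3 h phases, 30 min washout, alternating
first mode (1:1 allocation), mean respiratory rate 18/min with 20 % CV
gamma inter-breath jitter, per-arm zone occupancy ≈ (0.46, 0.20, 0.34),
manual interventions ≈ 1.3 vs 2.1 per 3 h phase, ≈ 34 automated changes
per phase in the automated arm only, and ≈ 6.9 vs 1.4 alarm episodes per
phase with mean durations ≈ 57 s vs 94 s. Set PEEP moves inside a 5–12
cm H₂O corridor (lower bound 5 cm H₂O, upper bound mid-range of the
10–15 cm H₂O limits used clinically).

Mechanics worth knowing:

* **Zone-preimage sampling.** A target zone is drawn per dwell period
  (exponential, mean 120 s — this creates the serial correlation real
  SpO₂ traces have; 0 gives i.i.d. draws for variance checks), then
  (SpO₂, PEEP, FiO₂) is drawn uniformly from that zone's preimage under
  the shipped table, computed by brute-force sweep of the integer grid.
  Classification of every generated breath is therefore known by
  construction, and the stored ground truth (realized occupancy per phase)
  is recovered by the pipeline exactly, up to breaths lost to missing
  SpO₂ if a missing rate is configured.
* **Events.** Setting changes and alarms are Poisson in number per phase,
  placed with a minimum spacing of 90 s (beyond the 60 s coalescence
  window) and away from phase boundaries, with magnitudes above the
  detection thresholds — so in noise-free mode (`rr_jitter = 0`) detected
  counts equal ground truth exactly. Washout is event-quiet.
* **Seeding.** Patient *i* uses `SeedSequence(entropy=seed, spawn_key=(i,))`;
  cohorts are byte-reproducible and patients independent.

What the generator does **not** emulate: controller dynamics (it mimics
only the observable log signature of frequent small automated changes),
physiological coupling between settings and saturation, drift within a
phase, and carryover between phases. Passing recovery tests therefore
demonstrates that the pipeline measures what the log contains — not that
any clinical effect exists.

## Numerical and design choices

* Half-open interval convention everywhere time is windowed.
* Breath-duration cap 15 s; last breath of a segment takes the median
  duration; durations are undefined (missing, with warning) for
  single-breath segments.
* Missing-value tokens on ingestion: empty cell, `NA`, `NaN`
  (case-insensitive); any other non-numeric token drops the row and is
  counted in the parse report (`rows_read = rows_kept + rows_dropped`).
* Timestamps: numeric seconds pass through; ISO-8601 datetimes are
  normalised to Unix seconds so a cohort shares one time axis.
* Exact/approximate crossover for the signed-rank test at m = 20, chosen
  so the exact path stays sub-second while covering any plausible
  crossover cohort size where exactness matters.
* Outputs are deterministic given inputs and config; the provenance hash
  excludes the output directory so relocating a run does not change its
  content.

Problem sizes used by the test suite and the acceptance script — a
62,000-point classification sweep, a ~20,000-breath recovery patient, an
8-patient noise-free event cohort, a 53-patient full-scale cohort, 100
enumeration cross-checks and 1,000 null replicates — were chosen as the
smallest sizes at which each property is sharp (e.g. ±2 percentage points
of occupancy is > 4 binomial standard errors at 10,000 i.i.d. breaths).

## Limitations

* The zone table is a reconstruction; sites using different SpO₂ targets
  (e.g. COPD protocols) must supply their own table — the machinery treats
  it as data.
* Arterial-blood-gas-based oxygenation (PaO₂/FiO₂) is out of scope; the
  classification uses pulse-oximetry SpO₂ only.
* The alarm flag is binary; alarm causes are not classified.
* No period, carryover or mixed-effects modelling: the analysis is the
  plain paired comparison the crossover design supports.
* Binary vendor dumps and waveform data are not parsed; input is CSV with
  a configurable column mapping.
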