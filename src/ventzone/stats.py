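"""Paired crossover comparison and descriptive summaries.

The design is a two-period crossover, so every endpoint is compared within
patient: differences ``d_i = automated_i - conventional_i`` feed a Wilcoxon
signed-rank test.  The exact null distribution of the positive-rank sum
``W+`` is computed by convolving over all ``2^m`` sign assignments of the
ranked absolute differences (realised as a dynamic program over the doubled
— hence integer — mid-ranks, which is arithmetically identical to the full
enumeration); for m above a crossover (default 20) a normal approximation
with tie-corrected variance and continuity correction is used instead.

Zero differences are discarded by default (classic Wilcoxon); the Pratt
policy (rank zeros, then drop their ranks) is available.  Descriptives
follow the median [q1-q3] / mean (sd) presentation, with linear-interpolation
quartiles and an n-1 standard deviation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

EXACT_CROSSOVER_M = 20  # exact enumeration up to this many non-zero pairs


@dataclasses.dataclass
class PairedSample:
    """Per-patient endpoint values under both arms."""

    patient_ids: list[str]
    automated: np.ndarray
    conventional: np.ndarray

    def __post_init__(self) -> None:
        self.automated = np.asarray(self.automated, float)
        self.conventional = np.asarray(self.conventional, float)
        if not (len(self.patient_ids) == len(self.automated)
                == len(self.conventional)):
            raise ValidationError("PairedSample arrays must have equal length")


@dataclasses.dataclass
class Descriptives:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float


@dataclasses.dataclass
class ComparisonResult:
    n_pairs_used: int
    n_pairs_dropped: int  # pairs with a missing member
    statistic: float      # W+ = sum of ranks of positive differences
    p_value: float
    automated: Descriptives
    conventional: Descriptives


def describe(values: Sequence[float] | np.ndarray) -> Descriptives:
    """Median, quartiles (linear interpolation), mean and n-1 sd.

    Missing values are removed first; an empty input yields all-NaN fields,
    a single value an sd of NaN.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        nan = float("nan")
        return Descriptives(0, nan, nan, nan, nan, nan)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
    return Descriptives(len(v), float(med), float(q1), float(q3),
                        float(np.mean(v)), sd)


def _signed_ranks(d: np.ndarray, zero_policy: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Mid-ranks of |d| and signs for the non-zero differences.

    Returns (ranks_of_nonzero, signs_of_nonzero, n_zeros).  Under
    ``wilcoxon_discard`` zeros are removed before ranking; under ``pratt``
    zeros take part in the ranking and their ranks are then dropped.
    """
    zeros = d == 0.0
    n_zeros = int(zeros.sum())
    if zero_policy == "wilcoxon_discard":
        dnz = d[~zeros]
        ranks = sps.rankdata(np.abs(dnz))
        return ranks, np.sign(dnz), n_zeros
    if zero_policy == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        return ranks_all[~zeros], np.sign(d[~zeros]), n_zeros
    raise ValidationError(f"unknown zero_policy {zero_policy!r}")


def exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ over all sign assignments of ``ranks``.

    The distribution of W+ is built by dynamic-programming convolution over
    the doubled ranks (mid-ranks are multiples of 1/2, so doubling makes
    them integers); this enumerates all 2^m assignments without listing
    them.  p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    r2 = np.rint(2.0 * np.asarray(ranks, float)).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:total + 1 - r].copy()
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    lower = counts[:w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _approx_signed_rank_p(ranks: np.ndarray, signs: np.ndarray,
                          w_plus: float, zero_policy: str,
                          n_zeros: int) -> float:
    """Normal approximation with tie-corrected variance + continuity correction."""
    m = len(ranks)
    if zero_policy == "pratt" and n_zeros:
        n_all = m + n_zeros
        mu = (n_all * (n_all + 1) - n_zeros * (n_zeros + 1)) / 4.0
        var = (n_all * (n_all + 1) * (2 * n_all + 1)
               - n_zeros * (n_zeros + 1) * (2 * n_zeros + 1)) / 24.0
    else:
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    # continuity correction of 0.5 toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank(
    sample: PairedSample,
    zero_policy: str = "wilcoxon_discard",
    mode: str = "auto",
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on automated - conventional.

    ``mode``: ``exact`` (full sign-assignment distribution), ``normal_approx``
    or ``auto`` (exact for at most ``EXACT_CROSSOVER_M`` non-zero pairs).
    All differences zero gives p = 1.0 with a degeneracy warning; no usable
    pair at all raises :class:`ValidationError`.
    """
    auto = np.asarray(sample.automated, float)
    conv = np.asarray(sample.conventional, float)
    usable = ~(np.isnan(auto) | np.isnan(conv))
    n_dropped = int((~usable).sum())
    d = auto[usable] - conv[usable]
    if len(d) == 0:
        raise ValidationError("no complete pairs to compare")

    desc_a = describe(auto[usable])
    desc_c = describe(conv[usable])

    ranks, signs, n_zeros = _signed_ranks(d, zero_policy)
    m = len(ranks)
    if m == 0:
        warnings.warn("all paired differences are zero: degenerate sample",
                      stacklevel=2)
        return ComparisonResult(len(d), n_dropped, 0.0, 1.0, desc_a, desc_c)

    w_plus = float(ranks[signs > 0].sum())
    if mode == "auto":
        mode = "exact" if m <= EXACT_CROSSOVER_M else "normal_approx"
    if mode == "exact":
        p = exact_signed_rank_p(ranks, w_plus)
    elif mode == "normal_approx":
        p = _approx_signed_rank_p(ranks, signs, w_plus, zero_policy, n_zeros)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return ComparisonResult(len(d), n_dropped, w_plus, p, desc_a, desc_c)


# -- endpoint tables -------------------------------------------------------

def _comparison_row(ids: list[str], auto: np.ndarray, conv: np.ndarray,
                    alpha: float = 0.05, **meta) -> dict:
    usable = ~(np.isnan(np.asarray(auto, float)) | np.isnan(np.asarray(conv, float)))
    row = dict(meta)
    if usable.sum() < 2:
        for arm in ("auto", "conv"):
            for f in ("median", "q1", "q3", "mean", "sd"):
                row[f"{arm}_{f}"] = float("nan")
        row.update(n_pairs=int(usable.sum()), statistic=float("nan"),
                   p_value=float("nan"), significant=False)
        return row
    res = wilcoxon_signed_rank(PairedSample(ids, auto, conv))
    for arm, desc in (("auto", res.automated), ("conv", res.conventional)):
        row[f"{arm}_median"] = desc.median
        row[f"{arm}_q1"] = desc.q1
        row[f"{arm}_q3"] = desc.q3
        row[f"{arm}_mean"] = desc.mean
        row[f"{arm}_sd"] = desc.sd
    row.update(n_pairs=res.n_pairs_used, statistic=res.statistic,
               p_value=res.p_value, significant=bool(res.p_value < alpha))
    return row


def compare_all_endpoints(summaries, event_counts, alpha: float = 0.05):
    """Occupancy and intervention/alarm comparison tables across the cohort.

    Parameters
    ----------
    summaries
        Sequence of :class:`ventzone.aggregation.PatientSummary`.
    event_counts
        Concatenated per-phase event-count frame from
        :func:`ventzone.events.count_events_per_phase` over all patients.

    Returns
    -------
    (zone_table, event_table)
        ``zone_table``: one row per view x metric x zone with per-arm
        median/IQR/mean/sd and the paired p.  ``event_table``: the same for
        manual changes, automated changes, alarm count and alarm minutes.
        The significance flag at ``alpha`` is annotation only; no row is
        filtered and no multiplicity correction is applied.
    """
    import pandas as pd

    from . import zones
    from .aggregation import VIEWS

    if len(summaries) < 2:
        raise ValidationError("paired comparison needs at least 2 patients")
    ids = [s.patient_id for s in summaries]

    zone_rows = []
    for view in VIEWS:
        for metric in ("breaths", "time"):
            for zone in zones.ZONES:
                def pick(s, phase):
                    ep = s.phases[phase]
                    store = ep.pct_breaths if metric == "breaths" else ep.pct_time
                    return store[view][zone]
                auto = np.array([pick(s, "automated") for s in summaries])
                conv = np.array([pick(s, "conventional") for s in summaries])
                zone_rows.append(_comparison_row(
                    ids, auto, conv, alpha=alpha,
                    view=view, metric=metric, zone=zone))
    zone_table = pd.DataFrame(zone_rows)

    ec = event_counts[event_counts["phase"] != "washout"]
    pivot = ec.pivot_table(index="patient_id", columns="phase",
                           values=["n_manual", "n_automated", "n_alarms",
                                   "alarm_minutes"], aggfunc="sum")
    event_rows = []
    for endpoint, label in (("n_automated", "automated_changes"),
                            ("n_manual", "manual_changes"),
                            ("n_alarms", "alarm_count"),
                            ("alarm_minutes", "alarm_minutes")):
        sub = pivot[endpoint].reindex(ids)
        auto = sub.get("automated", pd.Series(np.nan, index=ids)).to_numpy(float)
        conv = sub.get("conventional", pd.Series(np.nan, index=ids)).to_numpy(float)
        event_rows.append(_comparison_row(ids, auto, conv, alpha=alpha,
                                          endpoint=label))
    event_table = pd.DataFrame(event_rows)
    return zone_table, event_table


# -- simulation harnesses --------------------------------------------------

def type_i_error_rate(n_pairs: int = 50, n_replicates: int = 1000,
                      alpha: float = 0.05,
                      rng: np.random.Generator | None = None) -> float:
    """Null rejection rate: both arms drawn from the same distribution."""
    rng = rng or np.random.default_rng(0)
    rejections = 0
    ids = [str(i) for i in range(n_pairs)]
    for _ in range(n_replicates):
        a = rng.normal(size=n_pairs)
        b = rng.normal(size=n_pairs)
        res = wilcoxon_signed_rank(PairedSample(ids, a, b))
        rejections += res.p_value < alpha
    return rejections / n_replicates


def paired_shift_power(n_pairs: int = 50, shift: float = 2.0,
                       base_rate: float = 2.0, n_replicates: int = 200,
                       alpha: float = 0.05,
                       rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo power for a shift in Poisson event counts between arms."""
    rng = rng or np.random.default_rng(0)
    ids = [str(i) for i in range(n_pairs)]
    hits = 0
    for _ in range(n_replicates):
        a = rng.poisson(base_rate, size=n_pairs).astype(float)
        b = rng.poisson(base_rate + shift, size=n_pairs).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon_signed_rank(PairedSample(ids, a, b))
        hits += res.p_value < alpha
    return hits / n_replicates
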