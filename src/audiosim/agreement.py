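"""Method-agreement statistics for paired threshold measurements.

The unit of analysis is the ear x frequency cell: each usable pair of
thresholds (e.g. pure-tone audiometry vs mobile test, or mobile test vs
retest) contributes one record, and cells are treated as independent for all
confidence intervals.  That replicates the accounting of the study design
this package simulates (pooled n counts cells, e.g. 967 of 980), not a
statistical endorsement: within-subject correlation is ignored by design.

Differences are oriented as value_a - value_b; in the study pipeline side a
is pure-tone audiometry and side b the mobile test, so positive differences
mean the mobile test reads lower (better) than the clinic.

All internals are kept unrounded; rounding to the reporting precision
(0.1 dB, whole percent) happens only in :func:`format_agreement_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEFAULT_GRID, Audiogram, FrequencyGrid

#: Cumulative |difference| cutoffs reported by the agreement tables, dB.
CUMULATIVE_CUTOFFS = (5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class PairedRecord:
    subject_id: str
    ear: str
    frequency: int
    value_a: float
    value_b: float


@dataclass
class PairedMeasurements:
    """Matched threshold pairs; out-of-range cells are excluded at construction."""

    records: list[PairedRecord]
    label_a: str = "a"
    label_b: str = "b"
    discarded_a: int = 0
    discarded_b: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, frequency: int) -> "PairedMeasurements":
        return PairedMeasurements(
            [r for r in self.records if r.frequency == frequency],
            self.label_a, self.label_b)

    def values(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([r.value_a for r in self.records], dtype=float)
        b = np.array([r.value_b for r in self.records], dtype=float)
        return a, b

    def differences(self) -> np.ndarray:
        a, b = self.values()
        return a - b

    def swapped(self) -> "PairedMeasurements":
        return PairedMeasurements(
            [PairedRecord(r.subject_id, r.ear, r.frequency, r.value_b, r.value_a)
             for r in self.records],
            self.label_b, self.label_a, self.discarded_b, self.discarded_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.subject_id, r.ear, r.frequency, r.value_a, r.value_b)
             for r in self.records],
            columns=["subject_id", "ear", "frequency", "value_a", "value_b"])


def pair(audiograms_a: list[Audiogram], audiograms_b: list[Audiogram],
         label_a: str = "a", label_b: str = "b", *,
         grid: FrequencyGrid = DEFAULT_GRID) -> PairedMeasurements:
    """Match two audiogram sets cell by cell, discarding unusable sides.

    Both sides must cover the same (subject, ear) units; a cell enters the
    pairing only if it is in range on both sides, and the number of cells
    lost to each side is reported.
    """
    def index(ags):
        idx = {}
        for ag in ags:
            key = (ag.subject_id, ag.ear)
            if key in idx:
                raise ValueError(f"duplicate audiogram for {key}")
            idx[key] = ag
        return idx

    ia, ib = index(audiograms_a), index(audiograms_b)
    if set(ia) != set(ib):
        only = set(ia) ^ set(ib)
        raise ValueError(f"subject/ear units present on one side only: {sorted(only)}")
    records, disc_a, disc_b = [], 0, 0
    for key in sorted(ia):
        ag_a, ag_b = ia[key], ib[key]
        for f in grid:
            ua, ub = ag_a.usable(f), ag_b.usable(f)
            if ua and ub:
                records.append(PairedRecord(key[0], key[1], f,
                                            ag_a.thresholds[f], ag_b.thresholds[f]))
            else:
                disc_a += not ua
                disc_b += not ub
    return PairedMeasurements(records, label_a, label_b, disc_a, disc_b)


# ---------------------------------------------------------------------------
# confidence intervals from summary statistics


def mean_diff_ci(mean: float, sd: float, n: int, conf: float = 0.95
                 ) -> tuple[float, float]:
    """Normal-approximation CI for a mean: mean +/- z * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    z = stats.norm.ppf((1 + conf) / 2)
    half = z * sd / math.sqrt(n)
    return mean - half, mean + half


def sd_ci_chi2(sd: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Chi-square CI for a standard deviation (n - 1 degrees of freedom)."""
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    lo = sd * math.sqrt(df / stats.chi2.ppf((1 + conf) / 2, df))
    hi = sd * math.sqrt(df / stats.chi2.ppf((1 - conf) / 2, df))
    return lo, hi


# ---------------------------------------------------------------------------
# reliability coefficients (k = 2 raters/methods)


def _anova_ms(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Row and error mean squares of the two-way model without interaction."""
    n = a.size
    k = 2
    data = np.column_stack([a, b])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_err, n


def icc_consistency(pairs: PairedMeasurements, conf: float = 0.95
                    ) -> tuple[float, float, float]:
    """Two-way ICC for consistency of a single measurement, with F-based CI.

    ICC = (MS_rows - MS_err) / (MS_rows + (k - 1) MS_err) with k = 2; being a
    consistency coefficient it ignores constant shifts between the methods.
    The CI uses the F-ratio method with (n - 1) and (n - 1)(k - 1) degrees of
    freedom.
    """
    a, b = pairs.values()
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    ms_rows, ms_err, n = _anova_ms(a, b)
    k = 2
    if ms_rows + (k - 1) * ms_err <= 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0:
        return icc, icc, icc
    fobs = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    q = 1 - (1 - conf) / 2
    fl = fobs / stats.f.ppf(q, df1, df2)
    fu = fobs * stats.f.ppf(q, df2, df1)
    return icc, (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def cronbach_alpha(pairs: PairedMeasurements, conf: float = 0.95
                   ) -> tuple[float, float, float]:
    """Cronbach alpha for the two measurements, with Feldt F-interval CI.

    For k = 2 items, alpha = 2 (1 - (var_a + var_b) / var_(a+b)); on the same
    data it satisfies alpha = 2 ICC_c / (1 + ICC_c) with the consistency ICC.
    """
    a, b = pairs.values()
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    n = a.size
    var_sum = float(np.var(a + b, ddof=1))
    if var_sum == 0:
        raise ValueError("zero variance of sums: alpha undefined")
    alpha = 2.0 * (1.0 - (float(np.var(a, ddof=1)) + float(np.var(b, ddof=1))) / var_sum)
    df1, df2 = n - 1, n - 1
    q = 1 - (1 - conf) / 2
    lo = 1 - (1 - alpha) * stats.f.ppf(q, df1, df2)
    hi = 1 - (1 - alpha) / stats.f.ppf(q, df2, df1)
    return alpha, lo, hi


# ---------------------------------------------------------------------------
# agreement tables


@dataclass
class AgreementRow:
    """One row of an agreement table (a frequency, or the pooled 'Total')."""

    frequency: int | str
    n: int
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    sd_diff: float
    sd_diff_ci: tuple[float, float]
    mean_abs_diff: float
    mean_abs_diff_ci: tuple[float, float]
    icc: float | None
    icc_ci: tuple[float, float] | None
    cumulative: dict[int, float] = field(default_factory=dict)  # |d| <= c, percent


def _row(pairs: PairedMeasurements, label: int | str, conf: float) -> AgreementRow:
    d = pairs.differences()
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    absd = np.abs(d)
    mad = float(absd.mean())
    mad_sd = float(absd.std(ddof=1))
    try:
        icc, lo, hi = icc_consistency(pairs, conf)
        icc_ci = (lo, hi)
    except ValueError:
        icc, icc_ci = None, None
    cumulative = {c: 100.0 * float((absd <= c).mean()) for c in CUMULATIVE_CUTOFFS}
    return AgreementRow(
        frequency=label, n=n, mean_diff=mean,
        mean_diff_ci=mean_diff_ci(mean, sd, n, conf) if sd >= 0 else (mean, mean),
        sd_diff=sd, sd_diff_ci=sd_ci_chi2(sd, n, conf),
        mean_abs_diff=mad, mean_abs_diff_ci=mean_diff_ci(mad, mad_sd, n, conf),
        icc=icc, icc_ci=icc_ci, cumulative=cumulative)


def summarize(pairs: PairedMeasurements, per_frequency: bool = True,
              conf: float = 0.95, *, grid: FrequencyGrid = DEFAULT_GRID
              ) -> list[AgreementRow]:
    """Agreement table: per-frequency rows (optional) plus the pooled row.

    Reports, per row: n, mean difference (a - b) with normal CI, SD of the
    differences with chi-square CI, mean absolute difference with normal CI,
    the consistency ICC with F-based CI, and the cumulative percentage of
    |differences| within 5..30 dB.
    """
    if len(pairs) == 0:
        raise ValueError("no paired records")
    rows: list[AgreementRow] = []
    if per_frequency:
        for f in grid:
            sub = pairs.subset(f)
            if len(sub):
                rows.append(_row(sub, f, conf))
    rows.append(_row(pairs, "Total", conf))
    return rows


def format_agreement_table(rows: list[AgreementRow]) -> pd.DataFrame:
    """Render rows at reporting precision: 0.1 dB for levels, whole percent."""
    def ci(pair):  # "(lo-hi)" with 0.1 dB precision
        return f"({pair[0]:.1f} to {pair[1]:.1f})"

    out = []
    for r in rows:
        rec = {
            "frequency": r.frequency, "n": r.n,
            "mean_diff": round(r.mean_diff, 1), "mean_diff_ci": ci(r.mean_diff_ci),
            "sd": round(r.sd_diff, 1), "sd_ci": ci(r.sd_diff_ci),
            "mean_abs_diff": round(r.mean_abs_diff, 1),
            "mean_abs_diff_ci": ci(r.mean_abs_diff_ci),
            "icc": None if r.icc is None else round(r.icc, 2),
            "icc_ci": None if r.icc_ci is None else
                      f"({r.icc_ci[0]:.2f} to {r.icc_ci[1]:.2f})",
        }
        for c, p in r.cumulative.items():
            rec[f"within_{c}dB_pct"] = round(p)
        out.append(rec)
    return pd.DataFrame(out)


def bland_altman(pairs: PairedMeasurements, per_frequency: bool = True, *,
                 grid: FrequencyGrid = DEFAULT_GRID
                 ) -> dict[int | str, tuple[float, float, float]]:
    """Bland-Altman limits of agreement: mean difference +/- 1.96 SD.

    Returns {frequency or 'Total': (mean_diff, lower_limit, upper_limit)};
    the limits always bracket the mean.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    out: dict[int | str, tuple[float, float, float]] = {}
    targets = ([(f, pairs.subset(f)) for f in grid] if per_frequency else [])
    targets.append(("Total", pairs))
    for label, sub in targets:
        if len(sub) < 2:
            continue
        d = sub.differences()
        m, s = float(d.mean()), float(d.std(ddof=1))
        out[label] = (m, m - 1.96 * s, m + 1.96 * s)
    return out


@dataclass
class OrderEffectResult:
    mean_1: float
    ci_1: tuple[float, float]
    mean_2: float
    ci_2: tuple[float, float]
    t_stat: float
    p_value: float
    pool: bool


def order_effect(diffs_group1, diffs_group2, alpha_level: float = 0.05
                 ) -> OrderEffectResult:
    """Compare mean differences between examination-order groups.

    Welch's two-sample t-test on the paired differences of the two order
    groups (clinic-first vs mobile-first); if the groups do not differ at
    ``alpha_level`` the analysis pools them.
    """
    d1 = np.asarray(diffs_group1, dtype=float)
    d2 = np.asarray(diffs_group2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("both groups must be non-empty")
    t, p = stats.ttest_ind(d1, d2, equal_var=False)
    return OrderEffectResult(
        mean_1=float(d1.mean()),
        ci_1=mean_diff_ci(float(d1.mean()), float(d1.std(ddof=1)), d1.size),
        mean_2=float(d2.mean()),
        ci_2=mean_diff_ci(float(d2.mean()), float(d2.std(ddof=1)), d2.size),
        t_stat=float(t), p_value=float(p), pool=bool(p >= alpha_level))
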