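"""Hearing-loss screening criterion, diagnostic accuracy and power.

The screening rule classifies an ear as hearing-impaired when the threshold
strictly exceeds 30 dB at any of 500, 1000 or 2000 Hz, or strictly exceeds
25 dB at more than one of those frequencies, or strictly exceeds 50 dB at
4000 Hz.  "Normal hearing" in the cohort-description sense is the stricter
condition that every threshold on the full grid is at most 25 dB HL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DEFAULT_GRID, EARS, Audiogram, FrequencyGrid
from .cohort import DeviceInstance, ListenerProfile
from .procedures import ProcedureConfig, run_full_exam


@dataclass(frozen=True)
class ScreeningCriterion:
    """Threshold limits of the screening rule, dB on the measurement scale."""

    single_freq_limit: float = 30.0
    multi_freq_limit: float = 25.0
    f4k_limit: float = 50.0
    core_frequencies: tuple[int, ...] = (500, 1000, 2000)
    f4k: int = 4000

    def __post_init__(self) -> None:
        if min(self.single_freq_limit, self.multi_freq_limit, self.f4k_limit) <= 0:
            raise ValueError("limits must be positive")


@dataclass(frozen=True)
class ScreeningResult:
    unit_id: tuple[str, str]          # (subject, ear)
    label: str                        # "loss" | "no_loss"
    fired_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label == "loss") != bool(self.fired_rules):
            raise ValueError("label must be 'loss' iff some rule fired")


def classify_hearing_loss(audiogram: Audiogram,
                          criterion: ScreeningCriterion | None = None
                          ) -> ScreeningResult:
    """Apply the screening rule to one ear; "exceeded" is strict (>).

    All three rules are evaluated independently and every fired rule is
    listed.  A missing (or out-of-range) threshold at a required frequency
    is an error: the rule cannot be evaluated.
    """
    criterion = criterion or ScreeningCriterion()
    required = (*criterion.core_frequencies, criterion.f4k)
    missing = [f for f in required if not audiogram.usable(f)]
    if missing:
        raise ValueError(f"required frequencies unusable: {missing}")
    fired = []
    core = {f: audiogram.thresholds[f] for f in criterion.core_frequencies}
    if any(v > criterion.single_freq_limit for v in core.values()):
        fired.append("single_freq_gt_30")
    if sum(v > criterion.multi_freq_limit for v in core.values()) >= 2:
        fired.append("multi_freq_gt_25")
    if audiogram.thresholds[criterion.f4k] > criterion.f4k_limit:
        fired.append("f4k_gt_50")
    return ScreeningResult((audiogram.subject_id, audiogram.ear),
                           "loss" if fired else "no_loss", tuple(fired))


def classify_normal(audiogram: Audiogram, limit: float = 25.0, *,
                    grid: FrequencyGrid = DEFAULT_GRID) -> bool:
    """True iff every threshold on the full grid is <= 25 dB HL (inclusive)."""
    missing = [f for f in grid if not audiogram.usable(f)]
    if missing:
        raise ValueError(f"frequencies unusable: {missing}")
    return all(audiogram.thresholds[f] <= limit for f in grid)


def _wald_ci(k: int, n: int, conf: float) -> tuple[float, float]:
    p = k / n
    z = stats.norm.ppf((1 + conf) / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return max(0.0, 100 * (p - half)), min(100.0, 100 * (p + half))


def _wilson_ci(k: int, n: int, conf: float) -> tuple[float, float]:
    lo, hi = stats.binomtest(k, n).proportion_ci(conf, method="wilson")
    return 100 * lo, 100 * hi


def sens_spec(truth, predicted, conf: float = 0.95, *, method: str = "wald"
              ) -> dict:
    """Sensitivity and specificity (percent) with binomial CIs.

    ``truth`` and ``predicted`` are boolean vectors (True = loss).  CIs are
    Wald by default (clipped to [0, 100]); Wilson via ``method="wilson"``.
    Returns a dict with the 2x2 table and both metrics.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.size != p.size:
        raise ValueError("truth and predicted must have equal length")
    tp = int((t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())
    fp = int((~t & p).sum())
    if tp + fn == 0:
        raise ValueError("no positive cases in truth: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative cases in truth: specificity undefined")
    ci = _wilson_ci if method == "wilson" else _wald_ci
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": 100 * tp / (tp + fn),
        "sensitivity_ci": ci(tp, tp + fn, conf),
        "specificity": 100 * tn / (tn + fp),
        "specificity_ci": ci(tn, tn + fp, conf),
    }


def sample_size_paired(sd: float, effect: float, alpha: float = 0.05,
                       power: float = 0.8) -> int:
    """Paired-difference sample size, two-sided normal approximation.

    n = ceil( ((z_{1-alpha/2} + z_power) * sd / effect)^2 )  units (ears).
    With sd 8.42 dB, effect 2.0 dB, alpha 0.05 and power 0.8 this gives 140.
    """
    if sd <= 0 or effect <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("invalid sample-size parameters")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return math.ceil(((z_a + z_b) * sd / effect) ** 2)


def screening_experiment(cohort: list[ListenerProfile],
                         devices: dict[str, tuple[DeviceInstance, object]],
                         config: ProcedureConfig | None = None,
                         rng: np.random.Generator | None = None, *,
                         criterion: ScreeningCriterion | None = None,
                         conf: float = 0.95,
                         grid: FrequencyGrid = DEFAULT_GRID) -> dict:
    """Mobile screening accuracy against simulated clinical ground truth.

    For each subject, runs one pure-tone exam (truth) and one mobile exam on
    the subject's device (prediction), applies the screening criterion per
    ear, and returns sensitivity/specificity with CIs.  Ears where either
    method lacks a usable threshold at a required frequency are excluded and
    counted.  ``devices`` maps subject_id to (device instance, reference).
    """
    config = config or ProcedureConfig()
    rng = rng if rng is not None else np.random.default_rng()
    criterion = criterion or ScreeningCriterion()
    truth, pred, excluded = [], [], 0
    for listener in cohort:
        instance, reference = devices[listener.subject_id]
        pta, _ = run_full_exam(listener, procedure="pta", config=config,
                               rng=rng, grid=grid)
        mob, _ = run_full_exam(listener, instance, reference, "mobile",
                               config=config, rng=rng, grid=grid)
        for ear in EARS:
            try:
                t = classify_hearing_loss(pta[ear], criterion).label == "loss"
                p = classify_hearing_loss(mob[ear], criterion).label == "loss"
            except ValueError:
                excluded += 1
                continue
            truth.append(t)
            pred.append(p)
    result = sens_spec(truth, pred, conf)
    result["n_ears"] = len(truth)
    result["excluded_ears"] = excluded
    return result
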