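"""End-to-end study orchestration.

Reproduces, in silico, the design of the validation trial: a calibration
crowd measures devices of many models in uncontrolled conditions; model
references are estimated biologically; a 70-subject patient cohort is then
examined in a counterbalanced crossover (half clinic-first, half
mobile-first) with one pure-tone exam and a mobile test plus retest per
subject; finally the agreement tables, screening accuracy and discard
accounting are computed.

Randomness is organised as one global seed expanded into independent
per-stage, per-unit streams (devices, crowd, calibration by model, cohort,
exams by subject), so the report is deterministic given the seed and
independent of the order in which subjects are listed or processed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement
from .agreement import (AgreementRow, OrderEffectResult, PairedMeasurements,
                        cronbach_alpha, format_agreement_table, order_effect,
                        pair, summarize)
from .calibration import (CalibrationRegistry, LiteratureMedians,
                          ReferenceLevel, simulate_calibration_record)
from .cohort import (DEFAULT_CLASS_MIX, DeviceInstance, DeviceModel,
                     ListenerParams, ListenerProfile, generate_device_instance,
                     generate_listener, generate_crowd, make_device_model)
from .core import DEFAULT_GRID, EARS, Audiogram, FrequencyGrid, write_audiograms
from .procedures import ProcedureConfig, run_full_exam
from .screening import ScreeningCriterion, classify_hearing_loss, sens_spec

# stage tags for seed derivation
_ST_DEVICES, _ST_CROWD, _ST_CAL, _ST_COHORT, _ST_ASSIGN, _ST_EXAM = range(6)

#: Device-model popularity of the simulated cohort: 16 named models with the
#: observed per-model device counts plus 12 minor models of 2 devices each,
#: one handset per subject (70 in total).
DEFAULT_DEVICE_COUNTS = (7, 4, 4, 3, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2) + (2,) * 12


@dataclass
class StudyConfig:
    """Everything needed to reproduce a full simulated study."""

    seed: int = 0
    n_subjects: int = 70
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    listener: ListenerParams = field(default_factory=ListenerParams)
    crowd_size: int = 400
    contamination_rate: float = 0.26
    records_per_model: int = 15
    min_devices: int = 15
    device_counts: tuple[int, ...] = DEFAULT_DEVICE_COUNTS
    device_offset_sd: float = 5.0
    device_instance_sd: float = 2.0
    device_min_level: float = -10.0
    device_max_level: float = 80.0
    literature_median: float = 0.0
    procedure: ProcedureConfig = field(default_factory=ProcedureConfig)
    criterion: ScreeningCriterion = field(default_factory=ScreeningCriterion)
    conf: float = 0.95
    order_alpha: float = 0.05

    def __post_init__(self) -> None:
        if sum(self.device_counts) < self.n_subjects:
            raise ValueError("device plan covers fewer handsets than subjects")

    @property
    def grid(self) -> FrequencyGrid:
        return DEFAULT_GRID

    def medians(self) -> LiteratureMedians:
        return LiteratureMedians({f: self.literature_median for f in self.grid})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["device_counts"] = list(self.device_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "listener" in d and isinstance(d["listener"], dict):
            d["listener"] = ListenerParams(**d["listener"])
        if "procedure" in d and isinstance(d["procedure"], dict):
            d["procedure"] = ProcedureConfig(**d["procedure"])
        if "criterion" in d and isinstance(d["criterion"], dict):
            c = d["criterion"]
            c["core_frequencies"] = tuple(c.get("core_frequencies", (500, 1000, 2000)))
            d["criterion"] = ScreeningCriterion(**c)
        if "device_counts" in d:
            d["device_counts"] = tuple(d["device_counts"])
        return cls(**d)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


class UncalibratedStudyError(RuntimeError):
    pass


@dataclass
class StudyReport:
    """All tables and accounting of one simulated study run."""

    seed: int
    n_subjects: int
    cells_total: int
    order_split: tuple[int, int]                 # (pta-first, mobile-first)
    calibration: pd.DataFrame
    order_table: pd.DataFrame
    order_result: OrderEffectResult
    pta_vs_mobile: list[AgreementRow]
    retest: list[AgreementRow]
    alpha_pta_mobile: tuple[float, float, float]
    alpha_retest: tuple[float, float, float]
    screening: dict
    discards: dict
    pairs_pta_mobile: PairedMeasurements
    pairs_retest: PairedMeasurements
    audiograms: dict[str, list[Audiogram]]

    def _row_dict(self, r: AgreementRow) -> dict:
        return {
            "frequency": str(r.frequency), "n": r.n,
            "mean_diff": round(r.mean_diff, 4),
            "mean_diff_ci": [round(x, 4) for x in r.mean_diff_ci],
            "sd": round(r.sd_diff, 4), "sd_ci": [round(x, 4) for x in r.sd_diff_ci],
            "mean_abs_diff": round(r.mean_abs_diff, 4),
            "icc": None if r.icc is None else round(r.icc, 4),
            "icc_ci": None if r.icc_ci is None else [round(x, 4) for x in r.icc_ci],
            "cumulative": {str(k): round(v, 4) for k, v in r.cumulative.items()},
        }

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "cells_total": self.cells_total,
            "order_split": list(self.order_split),
            "calibration": self.calibration.to_dict(orient="records"),
            "order_pool": self.order_result.pool,
            "order_p_value": round(self.order_result.p_value, 6),
            "pta_vs_mobile": [self._row_dict(r) for r in self.pta_vs_mobile],
            "retest": [self._row_dict(r) for r in self.retest],
            "alpha_pta_mobile": [round(x, 4) for x in self.alpha_pta_mobile],
            "alpha_retest": [round(x, 4) for x in self.alpha_retest],
            "screening": {k: (list(np.round(v, 4)) if isinstance(v, tuple)
                              else (round(v, 4) if isinstance(v, float) else v))
                          for k, v in self.screening.items()},
            "discards": self.discards,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        format_agreement_table(self.pta_vs_mobile).to_csv(
            outdir / "pta_vs_mobile.csv", index=False)
        format_agreement_table(self.retest).to_csv(
            outdir / "test_retest.csv", index=False)
        self.order_table.to_csv(outdir / "order_comparison.csv", index=False)
        self.calibration.to_csv(outdir / "calibration_summary.csv", index=False)
        self.pairs_pta_mobile.to_frame().to_csv(
            outdir / "pairs_pta_mobile.csv", index=False)
        self.pairs_retest.to_frame().to_csv(outdir / "pairs_retest.csv", index=False)
        for name, ags in self.audiograms.items():
            write_audiograms(ags, outdir / f"audiograms_{name}.csv")


def _expand_device_plan(config: StudyConfig) -> list[str]:
    """Subject index -> model id, per the popularity plan."""
    assignment: list[str] = []
    for i, count in enumerate(config.device_counts):
        assignment.extend([f"M{i + 1:02d}"] * count)
    return assignment[: config.n_subjects]


def _calibrate_models(config: StudyConfig, crowd: list[ListenerProfile],
                      models: dict[str, DeviceModel]) -> CalibrationRegistry:
    registry = CalibrationRegistry(medians=config.medians(),
                                   min_devices=config.min_devices,
                                   grid=config.grid)
    for mi, (model_id, model) in enumerate(sorted(models.items())):
        rng = _rng(config.seed, _ST_CAL, mi)
        t = 0.0
        made = 0
        while made < config.records_per_model:
            listener = crowd[int(rng.integers(len(crowd)))]
            instance = generate_device_instance(model, rng)
            rec = simulate_calibration_record(model, instance, listener,
                                              config.procedure, rng,
                                              timestamp=t, grid=config.grid)
            t += 1.0
            if rec is not None:
                registry.add(rec)
                made += 1
    return registry


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the complete simulated study for one configuration.

    Fails with a clear message when any cohort device's model does not reach
    a valid calibration (fewer than ``min_devices`` distinct devices).
    """
    config = config or StudyConfig()
    grid = config.grid

    # --- devices and crowd calibration -----------------------------------
    model_ids = sorted({m for m in _expand_device_plan(config)})
    dev_rng = _rng(config.seed, _ST_DEVICES)
    models = {mid: make_device_model(
        mid, dev_rng, offset_sd=config.device_offset_sd,
        instance_sd=config.device_instance_sd,
        min_level=config.device_min_level, max_level=config.device_max_level,
        grid=grid) for mid in model_ids}
    crowd = generate_crowd(config.crowd_size, config.contamination_rate,
                           config.listener, _rng(config.seed, _ST_CROWD),
                           grid=grid)
    registry = _calibrate_models(config, crowd, models)
    for mid in model_ids:
        ref = registry.get(mid)
        if ref is None or not ref.valid:
            n = 0 if ref is None else ref.n_distinct_devices
            raise UncalibratedStudyError(
                f"model {mid} has only {n} distinct calibrated devices "
                f"(needs {config.min_devices})")
    calibration_df = pd.DataFrame(
        [{"model_id": mid, "n_records": registry.get(mid).n_records,
          "n_distinct_devices": registry.get(mid).n_distinct_devices,
          "valid": registry.get(mid).valid} for mid in model_ids])

    # --- cohort, handsets and counterbalanced order ----------------------
    cohort_rng = _rng(config.seed, _ST_COHORT)
    labels = sorted(config.class_mix)
    probs = np.array([config.class_mix[l] for l in labels])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    cohort = []
    for i in range(config.n_subjects):
        label = str(cohort_rng.choice(labels, p=probs))
        age = float(np.clip(cohort_rng.normal(36.0, 11.0), 18.0, 71.0))
        cohort.append(generate_listener(age, label, config.listener, cohort_rng,
                                        subject_id=f"S{i:03d}", grid=grid))
    plan = _expand_device_plan(config)
    handsets = {}
    for i, listener in enumerate(cohort):
        inst_rng = _rng(config.seed, _ST_ASSIGN, i)
        handsets[listener.subject_id] = generate_device_instance(
            models[plan[i]], inst_rng, instance_id=f"{plan[i]}-subj{i:03d}")
    perm = _rng(config.seed, _ST_ASSIGN).permutation(config.n_subjects)
    n_first = round(config.n_subjects / 2)
    pta_first = {f"S{i:03d}" for i in perm[:n_first]}

    # --- exams ------------------------------------------------------------
    pta_ags: list[Audiogram] = []
    test_ags: list[Audiogram] = []
    retest_ags: list[Audiogram] = []
    for i, listener in enumerate(cohort):
        rng = _rng(config.seed, _ST_EXAM, i)
        instance = handsets[listener.subject_id]
        reference = registry.get(instance.model_id)
        # same stream order regardless of assignment; the order group is an
        # analysis label (no carry-over effects are simulated)
        pta, _ = run_full_exam(listener, procedure="pta",
                               config=config.procedure, rng=rng, grid=grid)
        test, _ = run_full_exam(listener, instance, reference, "mobile",
                                config=config.procedure, rng=rng, grid=grid)
        retest, _ = run_full_exam(listener, instance, reference, "mobile",
                                  config=config.procedure, rng=rng, grid=grid)
        pta_ags.extend(pta.values())
        test_ags.extend(test.values())
        retest_ags.extend(retest.values())

    def n_flagged(ags: list[Audiogram]) -> int:
        return sum(len(ag.oor_flags) for ag in ags)

    cells_total = config.n_subjects * 2 * len(grid)
    discards = {"pta": n_flagged(pta_ags), "test": n_flagged(test_ags),
                "retest": n_flagged(retest_ags), "cells_per_method": cells_total}

    # --- statistics -------------------------------------------------------
    pairs_tm = pair(pta_ags, test_ags, "pta", "mobile", grid=grid)
    pairs_rr = pair(test_ags, retest_ags, "test", "retest", grid=grid)

    g1 = PairedMeasurements(
        [r for r in pairs_tm.records if r.subject_id in pta_first],
        "pta", "mobile")
    g2 = PairedMeasurements(
        [r for r in pairs_tm.records if r.subject_id not in pta_first],
        "pta", "mobile")
    order_res = order_effect(g1.differences(), g2.differences(), config.order_alpha)
    order_rows = []
    for f in grid:
        for gname, g in (("pta_first", g1), ("mobile_first", g2)):
            d = g.subset(f).differences()
            if d.size >= 2:
                lo, hi = agreement.mean_diff_ci(float(d.mean()),
                                                float(d.std(ddof=1)), d.size,
                                                config.conf)
                order_rows.append({"frequency": f, "group": gname, "n": d.size,
                                   "mean_diff": float(d.mean()),
                                   "ci_low": lo, "ci_high": hi})
    order_df = pd.DataFrame(order_rows)

    rows_tm = summarize(pairs_tm, conf=config.conf, grid=grid)
    rows_rr = summarize(pairs_rr, conf=config.conf, grid=grid)

    # --- screening --------------------------------------------------------
    truth, predicted, excluded = [], [], 0
    by_unit_pta = {(a.subject_id, a.ear): a for a in pta_ags}
    by_unit_mob = {(a.subject_id, a.ear): a for a in test_ags}
    for key in sorted(by_unit_pta):
        try:
            t = classify_hearing_loss(by_unit_pta[key], config.criterion).label == "loss"
            p = classify_hearing_loss(by_unit_mob[key], config.criterion).label == "loss"
        except ValueError:
            excluded += 1
            continue
        truth.append(t)
        predicted.append(p)
    screening = sens_spec(truth, predicted, config.conf)
    screening["n_ears"] = len(truth)
    screening["excluded_ears"] = excluded

    return StudyReport(
        seed=config.seed, n_subjects=config.n_subjects, cells_total=cells_total,
        order_split=(len(pta_first), config.n_subjects - len(pta_first)),
        calibration=calibration_df, order_table=order_df, order_result=order_res,
        pta_vs_mobile=rows_tm, retest=rows_rr,
        alpha_pta_mobile=cronbach_alpha(pairs_tm, config.conf),
        alpha_retest=cronbach_alpha(pairs_rr, config.conf),
        screening=screening, discards=discards,
        pairs_pta_mobile=pairs_tm, pairs_retest=pairs_rr,
        audiograms={"pta": pta_ags, "mobile_test": test_ags,
                    "mobile_retest": retest_ags})


def reproduce_study_shapes(config: StudyConfig | None = None) -> StudyReport:
    """Run the default-scale study (70 subjects) and sanity-check its shape.

    The report contains every table of the study design: the 980-cell
    accounting, the counterbalanced order comparison, the clinic-vs-mobile
    and test-retest agreement tables with cumulative difference
    distributions, reliability coefficients and screening accuracy.
    """
    config = config or StudyConfig()
    report = run_study(config)
    expected = config.n_subjects * 2 * len(config.grid)
    assert report.cells_total == expected
    assert len(report.pairs_pta_mobile) <= expected
    return report
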