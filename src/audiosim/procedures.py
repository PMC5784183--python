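"""Simulated measurement procedures.

Three procedures estimate the listener's hidden threshold from yes/no
responses:

* :func:`hughson_westlake` — the clinical bracketing staircase (10 dB down
  after a heard tone, 5 dB up after a miss; threshold = lowest level heard
  on at least 2 of up to 4 ascending presentations).
* :func:`self_adjust_test` — the mobile app's self-adjustment: the user
  steps the tone down in 5 dB steps while hearing it, up while not, and
  confirms "Barely audible" once the level immediately below the candidate
  was missed twice (two consistent reversals).
* :func:`bekesy_track` — the calibration self-measurement: the level falls
  in small ticks while the button is held (audible) and rises when released;
  the threshold is the mean of the midpoints of the last few reversal pairs.

Cross-hearing is modelled explicitly: without masking, the contralateral
cochlea receives the presented level minus the interaural attenuation and
may detect the tone; masking (triggered above 40 dB) removes that path
entirely.  The clinical audiometer is treated as perfectly calibrated, so
pure-tone audiometry measures on the true dB HL scale; the mobile chain maps
commanded dB mHL through the model's stored reference and the handset's
physical offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (ABOVE_MAX, BELOW_MIN, DEFAULT_GRID, EARS, Audiogram,
                   FrequencyGrid, IN_RANGE, other_ear, snap_to_grid)
from .cohort import DeviceInstance, ListenerProfile, respond


class UncalibratedModelError(RuntimeError):
    """Raised when a mobile test is attempted with an invalid reference."""


@dataclass(frozen=True)
class ProcedureConfig:
    """Parameters of the measurement procedures (levels in dB on the test scale)."""

    step_down: float = 10.0          # bracketing descent after a heard tone
    step_up: float = 5.0             # bracketing ascent after a miss
    self_adjust_step: float = 5.0    # app button step
    masking_trigger: float = 40.0    # contralateral masking above this level
    interaural_attenuation: float = 40.0
    start_level: float = 40.0
    ascents_required: int = 2        # of up to max_ascents ascending responses
    max_ascents: int = 4
    grid_step: float = 5.0
    pta_min_level: float = -10.0     # clinical audiometer output range
    pta_max_level: float = 110.0
    max_presentations: int = 200
    # Bekesy tracking
    bekesy_step: float = 1.0         # dB per tick (fixed rate, discretised)
    bekesy_start: float = 40.0
    bekesy_max_steps: int = 250
    bekesy_discard_reversals: int = 2
    bekesy_reversal_pairs: int = 4
    bekesy_settle_window: int = 100  # final ticks over which the track must settle
    bekesy_max_range: float = 15.0   # max level range (dB) in that window for validity

    def __post_init__(self) -> None:
        if min(self.step_down, self.step_up, self.self_adjust_step,
               self.bekesy_step) <= 0:
            raise ValueError("all steps must be positive")
        if self.ascents_required < 1 or self.max_ascents < self.ascents_required:
            raise ValueError("need 1 <= ascents_required <= max_ascents")


@dataclass
class MeasurementTrace:
    """Auditable staircase log: one (level, heard, masking_on) per presentation."""

    presentations: list[tuple[float, bool, bool]] = field(default_factory=list)
    final_level: float | None = None
    flag: str = IN_RANGE

    def add(self, level: float, heard: bool, masking_on: bool) -> None:
        self.presentations.append((level, heard, masking_on))

    @property
    def levels(self) -> list[float]:
        return [p[0] for p in self.presentations]


@dataclass
class StaircaseResult:
    level: float | None
    flag: str
    trace: MeasurementTrace

    @property
    def usable(self) -> bool:
        return self.flag == IN_RANGE and self.level is not None


def effective_level(presented: float, masking_on: bool,
                    interaural_attenuation: float = 40.0) -> tuple[float, float]:
    """Acoustic level reaching the test-ear and contralateral cochlea.

    The test ear receives the presented level.  Without masking the
    contralateral cochlea receives presented - interaural_attenuation
    (cross-hearing); with masking that path is removed entirely (-inf).
    """
    contra = -math.inf if masking_on else presented - interaural_attenuation
    return presented, contra


def _binaural_heard(listener: ListenerProfile, test_ear: str, frequency: int,
                    acoustic_level: float, masking_on: bool,
                    config: ProcedureConfig, session_offsets: dict[str, float],
                    rng: np.random.Generator) -> bool:
    """One presentation: heard if either cochlea's detector fires."""
    test_level, contra_level = effective_level(acoustic_level, masking_on,
                                               config.interaural_attenuation)
    heard = respond(listener, test_ear, frequency, test_level,
                    session_offsets[test_ear], rng)
    if contra_level > -math.inf:
        contra = other_ear(test_ear)
        heard = heard or respond(listener, contra, frequency, contra_level,
                                 session_offsets[contra], rng)
    return heard


def _zero_offsets() -> dict[str, float]:
    return {ear: 0.0 for ear in EARS}


def hughson_westlake(listener: ListenerProfile, ear: str, frequency: int,
                     config: ProcedureConfig | None = None,
                     rng: np.random.Generator | None = None,
                     session_offsets: dict[str, float] | None = None
                     ) -> StaircaseResult:
    """Clinical bracketing staircase on the dB HL scale.

    Descends ``step_down`` after each heard response and ascends ``step_up``
    after each miss, starting with a familiarisation descent from
    ``start_level``.  The threshold is the lowest level heard on at least
    ``ascents_required`` ascending presentations (and on at least half of
    them), out of up to ``max_ascents``.  Results are clamped to the
    audiometer's output range with an out-of-range flag when the rule cannot
    complete at a limit.
    """
    config = config or ProcedureConfig()
    rng = rng if rng is not None else np.random.default_rng()
    offsets = session_offsets if session_offsets is not None else _zero_offsets()
    lo, hi = config.pta_min_level, config.pta_max_level
    trace = MeasurementTrace()
    level = float(snap_to_grid(config.start_level, config.grid_step))
    n_asc: dict[float, int] = {}
    n_hit: dict[float, int] = {}
    prev_level: float | None = None
    floor_hears = 0
    ceil_misses = 0
    for _ in range(config.max_presentations):
        masking_on = level > config.masking_trigger
        heard = _binaural_heard(listener, ear, frequency, level, masking_on,
                                config, offsets, rng)
        trace.add(level, heard, masking_on)
        arrived_ascending = prev_level is not None and level > prev_level
        if arrived_ascending:
            n_asc[level] = n_asc.get(level, 0) + 1
            if heard:
                n_hit[level] = n_hit.get(level, 0) + 1
                if (n_hit[level] >= config.ascents_required
                        and 2 * n_hit[level] >= n_asc[level]
                        and n_asc[level] <= config.max_ascents):
                    trace.final_level, trace.flag = level, IN_RANGE
                    return StaircaseResult(level, IN_RANGE, trace)
        # out-of-range bookkeeping
        if level <= lo and heard:
            floor_hears += 1
            if floor_hears >= 2:
                trace.final_level, trace.flag = lo, BELOW_MIN
                return StaircaseResult(lo, BELOW_MIN, trace)
        else:
            floor_hears = 0
        if level >= hi and not heard:
            ceil_misses += 1
            if ceil_misses >= 2:
                trace.final_level, trace.flag = hi, ABOVE_MAX
                return StaircaseResult(hi, ABOVE_MAX, trace)
        else:
            ceil_misses = 0
        prev_level = level
        level = max(lo, level - config.step_down) if heard \
            else min(hi, level + config.step_up)
    # staircase failed to converge within the presentation budget
    flag = ABOVE_MAX if trace.presentations[-1][0] >= (lo + hi) / 2 else BELOW_MIN
    bound = hi if flag == ABOVE_MAX else lo
    trace.final_level, trace.flag = bound, flag
    return StaircaseResult(bound, flag, trace)


def self_adjust_test(listener: ListenerProfile, ear: str, frequency: int,
                     device_instance: DeviceInstance, reference,
                     config: ProcedureConfig | None = None,
                     rng: np.random.Generator | None = None,
                     session_offsets: dict[str, float] | None = None
                     ) -> StaircaseResult:
    """Self-adjustment test on the dB mHL scale of a calibrated device model.

    The commanded level is converted to an acoustic level at the ear through
    the level chain  acoustic = reference[f] + commanded - instance_offset[f],
    so with an exactly recovered reference the device plays at nominal level.
    The user confirms "Barely audible" at the first level heard whose next
    lower level was missed and then missed again on re-check (two consistent
    reversals).  Results are snapped to the grid; device output limits yield
    out-of-range flags.
    """
    config = config or ProcedureConfig()
    rng = rng if rng is not None else np.random.default_rng()
    offsets = session_offsets if session_offsets is not None else _zero_offsets()
    if reference is None or not getattr(reference, "valid", False):
        raise UncalibratedModelError(
            f"model {device_instance.model_id!r} has no valid reference level")
    ref = reference.reference[frequency]
    dev_off = device_instance.offset[frequency]
    lo, hi = device_instance.min_level, device_instance.max_level
    step = config.self_adjust_step
    trace = MeasurementTrace()
    level = float(snap_to_grid(min(max(config.start_level, lo), hi), config.grid_step))
    pending: float | None = None   # candidate level awaiting re-check below
    prev: tuple[float, bool] | None = None
    floor_hears = 0
    ceil_misses = 0
    for _ in range(config.max_presentations):
        masking_on = level > config.masking_trigger
        acoustic = ref + level - dev_off
        heard = _binaural_heard(listener, ear, frequency, acoustic, masking_on,
                                config, offsets, rng)
        trace.add(level, heard, masking_on)
        if pending is not None and level == pending - step:
            if not heard:
                final = float(snap_to_grid(pending, config.grid_step))
                trace.final_level, trace.flag = final, IN_RANGE
                return StaircaseResult(final, IN_RANGE, trace)
            pending = None  # heard after all: resume normal descent from here
        if heard:
            floor_hears = floor_hears + 1 if level <= lo else 0
            ceil_misses = 0
            if floor_hears >= 2:
                trace.final_level, trace.flag = lo, BELOW_MIN
                return StaircaseResult(lo, BELOW_MIN, trace)
            if (pending is None and prev is not None
                    and prev == (level - step, False)):
                pending = level           # heard right above a miss: verify below
            prev = (level, True)
            level = max(lo, level - step)
        else:
            ceil_misses = ceil_misses + 1 if level >= hi else 0
            floor_hears = 0
            if ceil_misses >= 2:
                trace.final_level, trace.flag = hi, ABOVE_MAX
                return StaircaseResult(hi, ABOVE_MAX, trace)
            prev = (level, False)
            level = min(hi, level + step)
    flag = ABOVE_MAX if trace.presentations[-1][0] >= (lo + hi) / 2 else BELOW_MIN
    bound = hi if flag == ABOVE_MAX else lo
    trace.final_level, trace.flag = bound, flag
    return StaircaseResult(bound, flag, trace)


def bekesy_track(listener: ListenerProfile, ear: str, frequency: int,
                 device_instance: DeviceInstance,
                 config: ProcedureConfig | None = None,
                 rng: np.random.Generator | None = None,
                 session_offset: float = 0.0) -> tuple[float | None, bool]:
    """Bekesy-style self-tracking on the device's raw level scale.

    The level falls by ``bekesy_step`` per tick while the tone is audible
    (button held) and rises while it is not, for a fixed number of ticks.
    The estimate is the mean of the midpoints of the last
    ``bekesy_reversal_pairs`` reversal pairs after discarding the first
    ``bekesy_discard_reversals`` reversals.  A track is invalid when it
    produces too few reversals or fails to settle: the level range over the
    final ``bekesy_settle_window`` ticks must stay within
    ``bekesy_max_range`` dB (an inattentive user's track keeps wandering).

    Returns (raw threshold in device units, valid).  Calibration tracking is
    monaural: near-threshold levels are too soft for cross-hearing to matter.
    """
    config = config or ProcedureConfig()
    rng = rng if rng is not None else np.random.default_rng()
    dev_off = device_instance.offset[frequency]
    level = config.bekesy_start
    lo_raw, hi_raw = -40.0, 130.0  # generous raw-scale travel limits
    prev_heard: bool | None = None
    reversals: list[float] = []
    need = config.bekesy_discard_reversals + 2 * config.bekesy_reversal_pairs

    def tail_mids() -> list[float]:
        tail = reversals[-2 * config.bekesy_reversal_pairs:]
        return [(tail[i] + tail[i + 1]) / 2.0 for i in range(0, len(tail), 2)]

    # the track always runs its full duration (fixed sweep rate for a fixed
    # time); only the last reversal pairs enter the estimate, so lapses
    # during the long initial descent cannot leave spurious high reversals
    # in the tail
    levels: list[float] = []
    for _ in range(config.bekesy_max_steps):
        heard = respond(listener, ear, frequency, level - dev_off,
                        session_offset, rng)
        levels.append(level)
        if prev_heard is not None and heard != prev_heard:
            reversals.append(level)
        prev_heard = heard
        level += -config.bekesy_step if heard else config.bekesy_step
        level = min(max(level, lo_raw), hi_raw)
    if len(reversals) < need:
        return None, False
    window = levels[-config.bekesy_settle_window:]
    if max(window) - min(window) > config.bekesy_max_range:
        return None, False
    return float(np.mean(tail_mids())), True


def run_full_exam(listener: ListenerProfile, device_instance: DeviceInstance | None = None,
                  reference=None, procedure: str = "pta",
                  config: ProcedureConfig | None = None,
                  rng: np.random.Generator | None = None, *,
                  grid: FrequencyGrid = DEFAULT_GRID,
                  collect_traces: bool = False
                  ) -> tuple[dict[str, Audiogram], dict]:
    """One complete exam: both ears, full grid, one fresh session offset per ear.

    ``procedure`` is ``"pta"`` (clinical bracketing, dB HL) or ``"mobile"``
    (self-adjustment on a calibrated device, dB mHL).  The session offset
    models headphone (re)positioning: it is drawn once per exam and ear and
    shifts all of that ear's effective thresholds coherently, which is what
    makes test and retest differ even for an unchanged listener.
    """
    if procedure not in ("pta", "mobile"):
        raise ValueError(f"unknown procedure {procedure!r}")
    config = config or ProcedureConfig()
    rng = rng if rng is not None else np.random.default_rng()
    session_offsets = {ear: float(rng.normal(0.0, listener.session_sd))
                       if listener.session_sd > 0 else 0.0 for ear in EARS}
    scale = "HL" if procedure == "pta" else "mHL"
    audiograms: dict[str, Audiogram] = {}
    traces: dict[tuple[str, int], MeasurementTrace] = {}
    for ear in EARS:
        thresholds: dict[int, int] = {}
        flags: dict[int, str] = {}
        for f in grid:
            if procedure == "pta":
                res = hughson_westlake(listener, ear, f, config, rng, session_offsets)
            else:
                if device_instance is None:
                    raise ValueError("mobile exam requires a device instance")
                res = self_adjust_test(listener, ear, f, device_instance,
                                       reference, config, rng, session_offsets)
            if res.flag == IN_RANGE:
                thresholds[f] = int(res.level)
            else:
                flags[f] = res.flag
            if collect_traces:
                traces[(ear, f)] = res.trace
        audiograms[ear] = Audiogram(listener.subject_id, ear, scale,
                                    thresholds, flags, grid)
    meta = {"session_offsets": session_offsets, "traces": traces}
    return audiograms, meta
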