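"""Synthetic listeners, patient cohorts, calibration crowds and devices.

The simulation's hidden state is a :class:`ListenerProfile`: continuous true
thresholds per ear and frequency plus the parameters of a yes/no psychometric
response model.  Every measurement procedure only ever sees single boolean
responses drawn from that model; the staircases then try to recover the
hidden thresholds on the 5 dB grid.

Hearing-loss archetypes are deliberately simple shapes (flat conductive
elevation, high-frequency sensorineural slope) whose mixture reproduces the
qualitative composition of an otolaryngology-clinic cohort: roughly half
normal-hearing, the rest sensorineural or conductive/mixed losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_GRID, EARS, FrequencyGrid

# ---------------------------------------------------------------------------
# psychometric response model


def _phi(x: float) -> float:
    """Standard normal CDF via erf (fast scalar path)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclass(frozen=True)
class ListenerParams:
    """Psychometric and session parameters shared by generated listeners.

    slope : dB
        Spread of the cumulative-normal psychometric function; 3 dB is a
        typical value for pure-tone detection.
    guess_rate, lapse_rate : probability
        Floor and ceiling of the psychometric function (false "I can hear"
        presses, missed audible tones).
    session_sd : dB
        SD of the between-session threshold shift (headphone repositioning
        etc.); drawn once per exam and ear.
    """

    slope: float = 3.0
    guess_rate: float = 0.02
    lapse_rate: float = 0.02
    session_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0 <= self.guess_rate <= 0.1 and 0 <= self.lapse_rate <= 0.1):
            raise ValueError("guess_rate and lapse_rate must be in [0, 0.1]")
        if self.session_sd < 0:
            raise ValueError("session_sd must be non-negative")


#: Deterministic listener parameters: step-function responses, no noise.
DETERMINISTIC = ListenerParams(slope=1e-6, guess_rate=0.0, lapse_rate=0.0,
                               session_sd=0.0)


@dataclass
class ListenerProfile:
    """Ground truth for one simulated participant."""

    subject_id: str
    age: float
    true_thresholds: dict[tuple[str, int], float]
    slope: float = 3.0
    lapse_rate: float = 0.02
    guess_rate: float = 0.02
    session_sd: float = 2.5
    self_reported_normal: bool = False
    hearing_class: str = "normal"

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.session_sd < 0:
            raise ValueError("slope must be > 0 and session_sd >= 0")
        if not (0 <= self.guess_rate <= 0.1 and 0 <= self.lapse_rate <= 0.1):
            raise ValueError("guess_rate and lapse_rate must be in [0, 0.1]")

    def threshold(self, ear: str, frequency: int) -> float:
        return self.true_thresholds[(ear, frequency)]


def detection_probability(listener: ListenerProfile, ear: str, frequency: int,
                          level: float, session_offset: float = 0.0) -> float:
    """P(hear) for one presentation at ``level`` dB at the given ear.

    P = guess + (1 - guess - lapse) * Phi((level - (T + session_offset)) / slope)

    where T is the listener's hidden threshold for (ear, frequency).  At
    level = T + session_offset and guess = lapse the probability is exactly
    one half, which is what the staircase procedures bracket.
    """
    if level == -math.inf:
        return listener.guess_rate
    x = (level - (listener.threshold(ear, frequency) + session_offset)) / listener.slope
    return listener.guess_rate + (1.0 - listener.guess_rate - listener.lapse_rate) * _phi(x)


def respond(listener: ListenerProfile, ear: str, frequency: int, level: float,
            session_offset: float, rng: np.random.Generator) -> bool:
    """Draw one yes/no response ("I can hear") for a single presentation."""
    return bool(rng.random() < detection_probability(listener, ear, frequency,
                                                     level, session_offset))


# ---------------------------------------------------------------------------
# hearing-loss archetypes


@dataclass(frozen=True)
class HearingClass:
    """Shape parameters of a hearing-loss archetype.

    flat_loss : (low, high) dB
        Uniform range of the flat elevation added at all frequencies.
    hf_slope : dB/octave
        Additional loss per octave above 1 kHz (sensorineural slope).
    asymmetry_sd : dB
        SD of a random interaural shift (half added to one ear, half
        subtracted from the other).
    severity_bases, severity_probs
        For sloping losses, the low-frequency anchor level is drawn
        N(base, 5^2) with base sampled from these severities.
    cell_noise_sd : dB
        Independent per-ear, per-frequency roughness of the audiogram.
    """

    label: str
    flat_loss: tuple[float, float] = (0.0, 0.0)
    hf_slope: float = 0.0
    asymmetry_sd: float = 0.0
    severity_bases: tuple[float, ...] = ()
    severity_probs: tuple[float, ...] = ()
    cell_noise_sd: float = 3.0


NORMAL = HearingClass(label="normal", cell_noise_sd=0.0)
SENSORINEURAL = HearingClass(
    label="sensorineural", hf_slope=10.0, asymmetry_sd=10.0,
    severity_bases=(20.0, 35.0, 50.0, 65.0),  # mild .. profound anchors
    severity_probs=(0.4, 0.3, 0.2, 0.1),
)
CONDUCTIVE_MIXED = HearingClass(
    label="conductive_mixed", flat_loss=(20.0, 50.0), asymmetry_sd=5.0,
)

CLASSES = {c.label: c for c in (NORMAL, SENSORINEURAL, CONDUCTIVE_MIXED)}

#: Cohort composition observed in the clinic cohort: 36 normal, 21
#: sensorineural, 13 conductive/mixed of 70 participants.
DEFAULT_CLASS_MIX = {"normal": 36 / 70, "sensorineural": 21 / 70,
                     "conductive_mixed": 13 / 70}

_TRUE_FLOOR, _TRUE_CEIL = -10.0, 115.0


def _draw_thresholds(hearing_class: HearingClass, rng: np.random.Generator,
                     grid: FrequencyGrid) -> dict[tuple[str, int], float]:
    t: dict[tuple[str, int], float] = {}
    if hearing_class.label == "normal":
        # N(5, 5^2) per cell, truncated to [-10, 20]: guarantees <= 25 dB HL
        for ear in EARS:
            for f in grid:
                v = rng.normal(5.0, 5.0)
                while not (-10.0 <= v <= 20.0):
                    v = rng.normal(5.0, 5.0)
                t[(ear, f)] = v
        return t
    if hearing_class.severity_bases:
        base = float(rng.choice(hearing_class.severity_bases,
                                p=hearing_class.severity_probs or None))
        anchor = rng.normal(base, 5.0)
    else:
        anchor = rng.uniform(*hearing_class.flat_loss)
    asym = rng.normal(0.0, hearing_class.asymmetry_sd) if hearing_class.asymmetry_sd else 0.0
    for ear_i, ear in enumerate(EARS):
        ear_shift = asym / 2.0 if ear_i == 0 else -asym / 2.0
        for f in grid:
            octaves_above_1k = max(0.0, math.log2(f / 1000.0))
            v = anchor + hearing_class.hf_slope * octaves_above_1k + ear_shift
            v += rng.normal(0.0, hearing_class.cell_noise_sd)
            t[(ear, f)] = float(np.clip(v, _TRUE_FLOOR, _TRUE_CEIL))
    return t


def generate_listener(age: float, hearing_class: str | HearingClass,
                      params: ListenerParams | None = None,
                      rng: np.random.Generator | None = None, *,
                      subject_id: str = "S000",
                      grid: FrequencyGrid = DEFAULT_GRID,
                      self_reported_normal: bool = False) -> ListenerProfile:
    """Draw one listener from a hearing-class archetype."""
    params = params or ListenerParams()
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(hearing_class, str):
        try:
            hearing_class = CLASSES[hearing_class]
        except KeyError:
            raise ValueError(f"unknown hearing class {hearing_class!r}") from None
    thresholds = _draw_thresholds(hearing_class, rng, grid)
    return ListenerProfile(
        subject_id=subject_id, age=age, true_thresholds=thresholds,
        slope=params.slope, lapse_rate=params.lapse_rate,
        guess_rate=params.guess_rate, session_sd=params.session_sd,
        self_reported_normal=self_reported_normal,
        hearing_class=hearing_class.label,
    )


def generate_cohort(n_subjects: int, class_mix: dict[str, float] | None = None,
                    params: ListenerParams | None = None,
                    rng: np.random.Generator | None = None, *,
                    grid: FrequencyGrid = DEFAULT_GRID) -> list[ListenerProfile]:
    """Generate a patient cohort with the given class mixture.

    Ages are N(36, 11^2) clipped to [18, 71], matching the trial cohort's
    age structure; class labels are i.i.d. draws from ``class_mix``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    mix = class_mix if class_mix is not None else DEFAULT_CLASS_MIX
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions must sum to 1, got {total}")
    rng = rng if rng is not None else np.random.default_rng()
    labels = sorted(mix)
    probs = np.array([mix[l] for l in labels])
    cohort = []
    for i in range(n_subjects):
        label = str(rng.choice(labels, p=probs))
        age = float(np.clip(rng.normal(36.0, 11.0), 18.0, 71.0))
        cohort.append(generate_listener(age, label, params, rng,
                                        subject_id=f"S{i:03d}", grid=grid))
    return cohort


def generate_crowd(n_users: int, contamination_rate: float = 0.26,
                   params: ListenerParams | None = None,
                   rng: np.random.Generator | None = None, *,
                   contaminant_classes: tuple[HearingClass, ...] = (
                       SENSORINEURAL, CONDUCTIVE_MIXED),
                   grid: FrequencyGrid = DEFAULT_GRID) -> list[ListenerProfile]:
    """Generate the self-selected calibration crowd.

    All users are aged 18-35 and declare themselves normal-hearing; a
    fraction ``contamination_rate`` are nevertheless drawn from hearing-loss
    archetypes.  The default contamination of 0.26 makes the 37th percentile
    of the mixed crowd coincide with the median of its clean part
    (0.37 = 0.5 * 0.74), which is the design logic of the biological
    calibration estimator.
    """
    if not (0 <= contamination_rate < 1):
        raise ValueError("contamination_rate must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    crowd = []
    for i in range(n_users):
        age = float(rng.integers(18, 36))
        if rng.random() < contamination_rate:
            cls = contaminant_classes[int(rng.integers(len(contaminant_classes)))]
        else:
            cls = NORMAL
        crowd.append(generate_listener(age, cls, params, rng,
                                       subject_id=f"U{i:05d}", grid=grid,
                                       self_reported_normal=True))
    return crowd


# ---------------------------------------------------------------------------
# devices


@dataclass(frozen=True)
class DeviceModel:
    """Acoustic identity of one phone model with its bundled headphones.

    ``true_offset`` is the extra drive level (dB, per frequency) the model
    needs to reach nominal output: a device playing raw level L produces a
    sound at L - true_offset dB on the listener's hearing-level scale.  This
    is the per-model quantity biological calibration must recover.
    """

    model_id: str
    true_offset: dict[int, float]
    min_level: float = -10.0
    max_level: float = 80.0
    instance_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.min_level >= self.max_level:
            raise ValueError("min_level must be below max_level")
        if self.instance_sd < 0:
            raise ValueError("instance_sd must be non-negative")


@dataclass(frozen=True)
class DeviceInstance:
    """One physical handset: model offset plus unit-to-unit deviation."""

    instance_id: str
    model_id: str
    offset: dict[int, float]
    min_level: float
    max_level: float


def make_device_model(model_id: str, rng: np.random.Generator, *,
                      offset_sd: float = 5.0, instance_sd: float = 2.0,
                      min_level: float = -10.0, max_level: float = 80.0,
                      grid: FrequencyGrid = DEFAULT_GRID) -> DeviceModel:
    """Draw a device model with per-frequency output offsets ~ N(0, offset_sd^2)."""
    offsets = {f: float(rng.normal(0.0, offset_sd)) for f in grid}
    return DeviceModel(model_id, offsets, min_level, max_level, instance_sd)


def generate_device_instance(model: DeviceModel, rng: np.random.Generator,
                             instance_id: str | None = None) -> DeviceInstance:
    """Draw one handset of a model: offset = true_offset + N(0, instance_sd^2)."""
    if instance_id is None:
        instance_id = f"{model.model_id}-{rng.integers(1 << 30)}"
    offset = {f: v + float(rng.normal(0.0, model.instance_sd)) if model.instance_sd > 0
              else v for f, v in model.true_offset.items()}
    return DeviceInstance(instance_id, model.model_id, offset,
                          model.min_level, model.max_level)
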