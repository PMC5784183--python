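"""Audiogram containers, unit conventions and CSV I/O.

All levels are hearing levels in decibels: dB HL for clinical pure-tone
audiometry, dB mHL ("mobile hearing level") for tests run on biologically
calibrated mobile devices.  Measured thresholds live on a 5 dB grid;
continuous levels exist only inside the listener simulation.

An out-of-range cell (a threshold the procedure could not bracket within the
output limits of the audiometer or device) carries a flag instead of a value
and is excluded from all agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

#: Test frequencies in Hz, low to high.
DEFAULT_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 6000, 8000)

EARS = ("left", "right")
SCALES = ("HL", "mHL")

IN_RANGE = "in_range"
ABOVE_MAX = "above_max"
BELOW_MIN = "below_min"
MISSING = "missing"
OOR_FLAGS = (ABOVE_MAX, BELOW_MIN)

#: Measurement resolution of both test procedures, dB.
GRID_STEP = 5


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered set of test frequencies in Hz.

    The default grid covers the conventional octave frequencies 250 Hz to
    8 kHz plus the half-octave points 6 kHz, as used by both the clinical
    and the mobile procedure.
    """

    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES

    def __post_init__(self) -> None:
        freqs = tuple(self.frequencies)
        if len(freqs) == 0:
            raise ValueError("frequency grid must not be empty")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freqs)

    def __iter__(self) -> Iterator[int]:
        return iter(self.frequencies)

    def __len__(self) -> int:
        return len(self.frequencies)

    def __contains__(self, frequency: object) -> bool:
        return frequency in self.frequencies


DEFAULT_GRID = FrequencyGrid()


def other_ear(ear: str) -> str:
    if ear not in EARS:
        raise ValueError(f"unknown ear {ear!r}")
    return "right" if ear == "left" else "left"


def snap_to_grid(level: float, step: float = GRID_STEP) -> int | float:
    """Snap a continuous level to the nearest multiple of ``step``.

    Exact midpoints round away from zero, so e.g. 12.5 dB snaps to 15 dB and
    -12.5 dB to -15 dB; this keeps the rule symmetric for negative levels.
    Returns an int whenever the snapped value is integral.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    k = math.floor(abs(level) / step + 0.5)
    snapped = math.copysign(k * step, level)
    if float(snapped).is_integer():
        return int(snapped)
    return snapped


@dataclass
class Audiogram:
    """Per-ear thresholds on the frequency grid, on a single level scale.

    ``thresholds`` holds only usable (in-range) values, integers on the 5 dB
    grid.  ``oor_flags`` records frequencies where the procedure ran against
    an output limit (``above_max`` / ``below_min``).  A frequency absent from
    both is simply missing; missing and out-of-range cells are treated
    identically by the statistics (both are discarded).
    """

    subject_id: str
    ear: str
    scale: str = "HL"
    thresholds: dict[int, int] = field(default_factory=dict)
    oor_flags: dict[int, str] = field(default_factory=dict)
    grid: FrequencyGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.ear not in EARS:
            raise ValueError(f"ear must be one of {EARS}, got {self.ear!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        for f, level in self.thresholds.items():
            if f not in self.grid:
                raise ValueError(f"threshold at non-grid frequency {f} Hz")
            if level % GRID_STEP != 0:
                raise ValueError(
                    f"threshold {level} dB at {f} Hz is not on the {GRID_STEP} dB grid"
                )
        for f, flag in self.oor_flags.items():
            if f not in self.grid:
                raise ValueError(f"flag at non-grid frequency {f} Hz")
            if flag not in OOR_FLAGS:
                raise ValueError(f"unknown out-of-range flag {flag!r}")
            if f in self.thresholds:
                raise ValueError(
                    f"frequency {f} Hz is flagged {flag} but also has a threshold"
                )

    def flag(self, frequency: int) -> str:
        """State of one cell: in_range, above_max, below_min or missing."""
        if frequency in self.thresholds:
            return IN_RANGE
        return self.oor_flags.get(frequency, MISSING)

    def usable(self, frequency: int) -> bool:
        return frequency in self.thresholds

    @property
    def n_usable(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class EarFreqObservation:
    """One usable ear-by-frequency threshold in long format.

    The pooled rows of the agreement tables count these records, one per
    ear x frequency cell (70 subjects x 2 ears x 7 frequencies = 980 cells
    before discards).
    """

    subject_id: str
    ear: str
    frequency: int
    value: float


def to_long(audiograms: Iterable[Audiogram]) -> list[EarFreqObservation]:
    """Flatten audiograms to one record per usable (in-range) cell."""
    out: list[EarFreqObservation] = []
    for ag in audiograms:
        for f in ag.grid:
            if ag.usable(f):
                out.append(EarFreqObservation(ag.subject_id, ag.ear, f, ag.thresholds[f]))
    return out


def _columns(grid: FrequencyGrid) -> tuple[list[str], list[str]]:
    thr = [f"hz{f}" for f in grid]
    flg = [f"flag{f}" for f in grid]
    return thr, flg


def write_audiograms(audiograms: Iterable[Audiogram], path: str | Path,
                     grid: FrequencyGrid = DEFAULT_GRID) -> None:
    """Write audiograms to CSV (UTF-8, one header row, empty cell = missing)."""
    thr_cols, flg_cols = _columns(grid)
    rows = []
    for ag in audiograms:
        row: dict[str, object] = {"subject_id": ag.subject_id, "ear": ag.ear,
                                  "scale": ag.scale}
        for f, tc, fc in zip(grid, thr_cols, flg_cols):
            row[tc] = ag.thresholds.get(f, "")
            row[fc] = ag.flag(f)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "ear", "scale", *thr_cols, *flg_cols])
    df.to_csv(path, index=False)


def read_audiograms(path: str | Path, grid: FrequencyGrid = DEFAULT_GRID) -> list[Audiogram]:
    """Read audiograms written by :func:`write_audiograms`.

    Raises ValueError naming the offending CSV line for malformed rows and
    rejects thresholds off the 5 dB grid or at unknown frequencies.
    """
    thr_cols, flg_cols = _columns(grid)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["subject_id", "ear", "scale", *thr_cols, *flg_cols]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"unknown columns (unrecognised frequencies?): {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    out: list[Audiogram] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        thresholds: dict[int, int] = {}
        flags: dict[int, str] = {}
        for f, tc, fc in zip(grid, thr_cols, flg_cols):
            cell = row[tc].strip()
            flag = row[fc].strip() or MISSING
            if cell:
                try:
                    level = float(cell)
                except ValueError:
                    raise ValueError(f"line {line}: non-numeric threshold {cell!r}") from None
                if level != int(level) or int(level) % GRID_STEP != 0:
                    raise ValueError(
                        f"line {line}: threshold {cell} dB at {f} Hz is off the "
                        f"{GRID_STEP} dB grid")
                if flag != IN_RANGE:
                    raise ValueError(
                        f"line {line}: cell at {f} Hz has a value but flag {flag!r}")
                thresholds[f] = int(level)
            elif flag in OOR_FLAGS:
                flags[f] = flag
            elif flag not in (MISSING, IN_RANGE):
                raise ValueError(f"line {line}: unknown flag {flag!r}")
        try:
            out.append(Audiogram(row["subject_id"], row["ear"], row["scale"],
                                 thresholds, flags, grid))
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from None
    return out
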