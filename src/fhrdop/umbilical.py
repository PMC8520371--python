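"""Umbilical-artery waveform typing for selective fetal growth restriction.

In monochorionic twins, selective fetal growth restriction (sFGR) — one
twin small for gestational age (SGA), i.e. estimated fetal weight below the
10th percentile for its gestational week — is graded by the end-diastolic
flow pattern of the umbilical artery Doppler:

* **Type I** — positive (normal) end-diastolic flow in every cycle;
* **Type II** — continuously absent or reversed end-diastolic flow;
* **Type III** — intermittently absent or reversed end-diastolic flow.

This module extracts per-cycle end-diastolic velocities (EDV) from a
velocity trace, applies the typing rule, evaluates the SGA screen against a
growth-percentile reference table, and can synthesise labelled traces for
testing the classifier end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .detect import InsufficientDataError

__all__ = [
    "UmbilicalCycleSeries",
    "SFGRTypeCall",
    "GrowthReference",
    "end_diastolic_velocities",
    "classify_sfgr_type",
    "is_sga",
    "synthesize_umbilical_trace",
    "DEFAULT_DEAD_BAND_CMS",
]

#: Velocities at or below this magnitude (cm/s) count as "absent" flow: a
#: dead band around zero, since clinical machines cannot resolve a true
#: zero velocity. Configurable per call.
DEFAULT_DEAD_BAND_CMS = 0.5

#: Fraction of each cardiac cycle treated as end-diastole.
_END_DIASTOLE_FRACTION = 0.2

MIN_CYCLES = 3


@dataclass
class UmbilicalCycleSeries:
    """Per-cardiac-cycle end-diastolic velocities (signed, cm/s)."""

    end_diastolic_velocity: np.ndarray

    def __post_init__(self) -> None:
        self.end_diastolic_velocity = np.asarray(
            self.end_diastolic_velocity, dtype=float
        )
        if not np.all(np.isfinite(self.end_diastolic_velocity)):
            raise ValueError("end-diastolic velocities must be finite")

    @property
    def n_cycles(self) -> int:
        return len(self.end_diastolic_velocity)


@dataclass
class SFGRTypeCall:
    """Result of umbilical-artery waveform typing."""

    type_label: str  # "I", "II" or "III"
    fraction_abnormal: float


class GrowthReference:
    """Gestational-week → 10th-percentile estimated fetal weight table.

    Weights must increase strictly with gestational week; queries between
    tabulated weeks are linearly interpolated.  The built-in
    :meth:`demo` table contains synthetic demonstration values of plausible
    magnitude for weeks 24–40 — substitute a population-appropriate growth
    standard (``from_csv`` with columns ``week,p10_weight_g``) for any real
    assessment.
    """

    def __init__(self, weeks, p10_weight_g) -> None:
        self.weeks = np.asarray(weeks, dtype=float)
        self.p10_weight_g = np.asarray(p10_weight_g, dtype=float)
        if len(self.weeks) != len(self.p10_weight_g) or len(self.weeks) < 2:
            raise ValueError("reference needs >= 2 (week, weight) rows")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if np.any(np.diff(self.p10_weight_g) <= 0):
            raise ValueError("percentile weights must increase with week")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GrowthReference":
        df = pd.read_csv(path, comment="#")
        return cls(df["week"].to_numpy(), df["p10_weight_g"].to_numpy())

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"week": self.weeks, "p10_weight_g": self.p10_weight_g}).to_csv(
            path, index=False
        )

    @classmethod
    def demo(cls) -> "GrowthReference":
        """Synthetic demonstration table (weeks 24–40, grams)."""
        weeks = np.arange(24, 41, 2)
        p10 = np.array([540, 710, 920, 1170, 1460, 1800, 2180, 2550, 2850], float)
        return cls(weeks, p10)

    def p10_at(self, gestational_week: float) -> float:
        if not self.weeks[0] <= gestational_week <= self.weeks[-1]:
            raise ValueError(
                f"gestational week {gestational_week:g} outside reference range "
                f"[{self.weeks[0]:g}, {self.weeks[-1]:g}]"
            )
        return float(np.interp(gestational_week, self.weeks, self.p10_weight_g))


def end_diastolic_velocities(
    velocity_trace,
    sample_rate_hz: float,
    heart_rate_bpm: float,
) -> UmbilicalCycleSeries:
    """Per-cycle end-diastolic velocities of an umbilical velocity trace.

    The trace is segmented into cardiac cycles of ``60 / heart_rate_bpm``
    seconds; the EDV of each cycle is the minimum velocity over its final
    20% (the end-diastolic interval).  At least :data:`MIN_CYCLES` complete
    cycles are required.
    """
    trace = np.asarray(velocity_trace, dtype=float)
    if sample_rate_hz <= 0 or heart_rate_bpm <= 0:
        raise ValueError("sample_rate_hz and heart_rate_bpm must be positive")
    cycle_len = 60.0 / heart_rate_bpm * sample_rate_hz
    n_cycles = int(len(trace) // cycle_len)
    if n_cycles < MIN_CYCLES:
        raise InsufficientDataError(
            f"trace covers {n_cycles} complete cycles; at least {MIN_CYCLES} required"
        )
    edv = np.empty(n_cycles)
    for i in range(n_cycles):
        start, stop = round(i * cycle_len), round((i + 1) * cycle_len)
        seg = trace[start:stop]
        tail = max(1, round(_END_DIASTOLE_FRACTION * len(seg)))
        edv[i] = seg[-tail:].min()
    return UmbilicalCycleSeries(end_diastolic_velocity=edv)


def classify_sfgr_type(
    series: UmbilicalCycleSeries,
    abnormal_threshold: float = 1.0,
    dead_band_cms: float = DEFAULT_DEAD_BAND_CMS,
) -> SFGRTypeCall:
    """Grade an umbilical EDV series into sFGR Doppler Types I–III.

    A cycle is abnormal when its EDV is at or below ``dead_band_cms``
    (absent or reversed flow).  No abnormal cycle → Type I; a fraction of
    abnormal cycles ≥ ``abnormal_threshold`` (default 1.0, i.e. every
    cycle, "continuous") → Type II; anything in between ("intermittent") →
    Type III.  The call is invariant to cycle order.
    """
    if series.n_cycles < MIN_CYCLES:
        raise InsufficientDataError(
            f"{series.n_cycles} cycles; at least {MIN_CYCLES} required"
        )
    if not 0.0 < abnormal_threshold <= 1.0:
        raise ValueError("abnormal_threshold must lie in (0, 1]")
    abnormal = series.end_diastolic_velocity <= dead_band_cms
    frac = float(abnormal.mean())
    if frac == 0.0:
        label = "I"
    elif frac >= abnormal_threshold:
        label = "II"
    else:
        label = "III"
    return SFGRTypeCall(type_label=label, fraction_abnormal=frac)


def is_sga(
    estimated_weight_g: float,
    gestational_week: float,
    reference: Optional[GrowthReference] = None,
) -> bool:
    """Small-for-gestational-age screen.

    True iff the estimated fetal weight is strictly below the reference
    10th percentile at that gestational week (linear interpolation between
    tabulated weeks).  With no reference given, the synthetic
    demonstration table is used.
    """
    if estimated_weight_g < 0:
        raise ValueError("estimated_weight_g must be non-negative")
    ref = reference if reference is not None else GrowthReference.demo()
    return estimated_weight_g < ref.p10_at(gestational_week)


def synthesize_umbilical_trace(
    sfgr_type: str,
    heart_rate_bpm: float = 140.0,
    n_cycles: int = 10,
    sample_rate_hz: float = 100.0,
    peak_velocity_cms: float = 40.0,
    normal_edv_cms: float = 10.0,
    reversed_edv_cms: float = -5.0,
    noise_cms: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic umbilical-artery velocity trace with a known sFGR type.

    Each cardiac cycle is a raised-cosine systolic peak decaying onto a
    diastolic plateau whose end value is set per cycle: ``normal_edv_cms``
    for all cycles (Type I), ``reversed_edv_cms`` for all (Type II), or
    alternating normal/reversed (Type III).  Optional Gaussian noise.
    """
    if sfgr_type not in ("I", "II", "III"):
        raise ValueError(f"sfgr_type must be 'I', 'II' or 'III', got {sfgr_type!r}")
    cycle_len = round(60.0 / heart_rate_bpm * sample_rate_hz)
    phase = np.arange(cycle_len) / cycle_len
    systole = np.where(phase < 0.4, 0.5 * (1 - np.cos(2 * np.pi * phase / 0.4)), 0.0)

    cycles = []
    for i in range(n_cycles):
        if sfgr_type == "I":
            edv = normal_edv_cms
        elif sfgr_type == "II":
            edv = reversed_edv_cms
        else:
            edv = normal_edv_cms if i % 2 == 0 else reversed_edv_cms
        # systolic pulse riding on a ramp from the previous plateau to edv
        diastolic = np.linspace(normal_edv_cms, edv, cycle_len)
        cycles.append(systole * (peak_velocity_cms - diastolic) + diastolic)
    trace = np.concatenate(cycles)
    if noise_cms > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_cms, len(trace))
    return trace
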