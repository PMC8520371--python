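"""Synthetic ultrasound-Doppler fetal heart signals with known ground truth.

A continuous-wave Doppler probe aimed at the fetal heart returns an echo
whose frequency is offset from the carrier by the Doppler shift

    f_D = 2 * v * f_0 * cos(theta) / c

where ``v`` is the velocity of the reflecting interface (the moving heart
wall), ``f_0`` the transmit frequency, ``theta`` the angle between the beam
and the motion, and ``c`` the speed of sound in tissue.  The factor 2
accounts for the two-way travel of the reflected wave.  The audible Doppler
signal is therefore an amplitude- and frequency-modulated tone whose
envelope repeats once per cardiac cycle — the periodicity that the
autocorrelation detector in :mod:`fhrdop.detect` exploits.

This module generates such signals with a known heart rate so that the
detector can be validated against ground truth: a parametric cardiac
velocity waveform (one raised-cosine systolic pulse per beat) is mapped
through the Doppler relation to an instantaneous frequency, modulated in
amplitude by the speed profile, and corrupted with additive white Gaussian
noise at a configurable signal-to-noise ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SOUND_SPEED_TISSUE_MPS",
    "DopplerConfig",
    "DopplerSignal",
    "doppler_shift",
    "cardiac_velocity_waveform",
    "synthesize_doppler",
]

#: Conventional speed of sound in soft tissue (m/s).
SOUND_SPEED_TISSUE_MPS = 1540.0

#: Fraction of the cardiac cycle occupied by the systolic velocity pulse.
SYSTOLIC_FRACTION = 0.3


class AliasingError(ValueError):
    """Sampling rate too low for the peak Doppler shift."""


@dataclass(frozen=True)
class DopplerConfig:
    """Parameters of a synthetic Doppler acquisition.

    Attributes
    ----------
    carrier_freq_hz:
        Ultrasound transmit frequency ``f_0`` (Hz).  Fetal Doppler probes
        typically run at 2–3 MHz.
    sound_speed_mps:
        Propagation speed ``c`` in tissue (m/s).
    beam_angle_rad:
        Angle ``theta`` between the beam axis and the direction of motion,
        in radians, restricted to [0, pi/2].
    sample_rate_hz:
        Audio sampling rate ``f_s`` of the demodulated Doppler signal (Hz).
    duration_s:
        Signal length in seconds.
    heart_rate_bpm:
        Ground-truth fetal heart rate (beats per minute).
    peak_velocity_mps:
        Peak tissue velocity of the cardiac wall motion (m/s).
    snr_db:
        Signal-to-noise ratio of the additive white Gaussian noise, in dB
        relative to the clean signal power.  ``math.inf`` means noiseless.
    seed:
        Seed for the noise generator; fixed seed gives identical samples.
    """

    carrier_freq_hz: float = 2.0e6
    sound_speed_mps: float = SOUND_SPEED_TISSUE_MPS
    beam_angle_rad: float = 0.0
    sample_rate_hz: float = 4000.0
    duration_s: float = 8.0
    heart_rate_bpm: float = 140.0
    peak_velocity_mps: float = 0.15
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carrier_freq_hz <= 0:
            raise ValueError("carrier_freq_hz must be positive")
        if self.sound_speed_mps <= 0:
            raise ValueError("sound_speed_mps must be positive")
        if not 0.0 <= self.beam_angle_rad <= math.pi / 2:
            raise ValueError("beam_angle_rad must lie in [0, pi/2]")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 30.0 <= self.heart_rate_bpm <= 300.0:
            raise ValueError("heart_rate_bpm must lie in [30, 300]")
        if self.peak_velocity_mps < 0:
            raise ValueError("peak_velocity_mps must be non-negative")

    def with_(self, **kwargs) -> "DopplerConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)


@dataclass
class DopplerSignal:
    """A sampled single-channel Doppler audio signal.

    ``truth_bpm`` carries the ground-truth heart rate for simulator output;
    it is ``None`` for signals read from disk.
    """

    samples: np.ndarray
    sample_rate_hz: float
    truth_bpm: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("DopplerSignal requires a 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("DopplerSignal samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


def doppler_shift(
    velocity_mps: float,
    carrier_freq_hz: float,
    beam_angle_rad: float = 0.0,
    sound_speed_mps: float = SOUND_SPEED_TISSUE_MPS,
):
    """Frequency offset of an echo from a reflector moving at ``velocity_mps``.

    Implements the reflected-wave relation ``f_D = 2 v f_0 cos(theta) / c``;
    the sign of the result follows the sign of the velocity (approaching
    reflectors raise the echo frequency).  Accepts scalar or array velocity.
    """
    if sound_speed_mps <= 0:
        raise ValueError("sound_speed_mps must be positive")
    v = np.asarray(velocity_mps, dtype=float)
    out = 2.0 * v * carrier_freq_hz * math.cos(beam_angle_rad) / sound_speed_mps
    return float(out) if np.isscalar(velocity_mps) else out


def cardiac_velocity_waveform(config: DopplerConfig) -> np.ndarray:
    """Per-sample cardiac wall velocity trace (m/s).

    One raised-cosine systolic pulse per beat, of width
    ``SYSTOLIC_FRACTION`` of the cycle, zero velocity in diastole.  The
    trace is periodic with fundamental period ``60 / heart_rate_bpm``
    seconds and peak magnitude ``peak_velocity_mps``.
    """
    t = np.arange(config.n_samples) / config.sample_rate_hz
    period_s = 60.0 / config.heart_rate_bpm
    phase = (t % period_s) / period_s
    pulse = np.where(
        phase < SYSTOLIC_FRACTION,
        0.5 * (1.0 - np.cos(2.0 * np.pi * phase / SYSTOLIC_FRACTION)),
        0.0,
    )
    return config.peak_velocity_mps * pulse


def synthesize_doppler(config: DopplerConfig) -> DopplerSignal:
    """Generate a synthetic Doppler audio signal for ``config``.

    The clean signal is a tone whose instantaneous frequency is the
    per-sample Doppler shift of the cardiac velocity trace, amplitude-
    modulated by the (normalised) speed profile so the audio pulses once
    per beat, as a real fetal Doppler does.  White Gaussian noise is added
    at ``snr_db`` relative to the clean signal power; output is
    reproducible for a fixed seed.

    Raises
    ------
    AliasingError
        If ``sample_rate_hz`` is not more than twice the peak Doppler
        shift, so the modulated tone cannot be represented.
    """
    v = cardiac_velocity_waveform(config)
    f_inst = doppler_shift(
        v, config.carrier_freq_hz, config.beam_angle_rad, config.sound_speed_mps
    )
    peak_shift = float(np.max(np.abs(f_inst))) if len(f_inst) else 0.0
    if peak_shift > 0 and config.sample_rate_hz <= 2.0 * peak_shift:
        raise AliasingError(
            f"sample_rate_hz={config.sample_rate_hz:g} Hz cannot represent a "
            f"peak Doppler shift of {peak_shift:g} Hz (need > {2*peak_shift:g} Hz)"
        )

    phase = 2.0 * np.pi * np.cumsum(f_inst) / config.sample_rate_hz
    if config.peak_velocity_mps > 0:
        amplitude = np.abs(v) / config.peak_velocity_mps
    else:
        amplitude = np.zeros_like(v)
    clean = amplitude * np.sin(phase)

    samples = clean
    if math.isfinite(config.snr_db):
        clean_power = float(np.mean(clean**2))
        noise_sigma = math.sqrt(clean_power / 10.0 ** (config.snr_db / 10.0))
        rng = np.random.default_rng(config.seed)
        samples = clean + rng.normal(0.0, noise_sigma, len(clean))

    return DopplerSignal(
        samples=samples,
        sample_rate_hz=config.sample_rate_hz,
        truth_bpm=config.heart_rate_bpm,
    )
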