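"""Signal file I/O and the reproducible fixture battery.

Signals travel as mono 16-bit PCM WAV or as a flat self-describing CSV
dialect: comment lines starting with ``#`` (the first carrying
``# sample_rate_hz=<f>``) followed by one sample per line.  CSV round-trips
exactly; WAV round-trips to within 16-bit quantisation.

:func:`generate_fixtures` writes the standard test battery — simulated
Doppler signals over a grid of heart rates and SNRs, umbilical traces of
each sFGR type, and the reference cohort summary tables — together with a
JSON manifest of the ground truth per file.  Byte-identical for a fixed
seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import cohortstats
from .simulate import DopplerConfig, DopplerSignal, synthesize_doppler
from .umbilical import GrowthReference, synthesize_umbilical_trace

__all__ = ["FormatError", "read_signal", "write_signal", "generate_fixtures"]

FIXTURE_HEART_RATES_BPM = (60.0, 120.0, 140.0, 160.0, 240.0)
FIXTURE_SNRS_DB = (float("inf"), 0.0, 10.0, 20.0)
FIXTURE_DURATION_S = 8.0


class FormatError(ValueError):
    """Unreadable, ambiguous or unsupported signal file."""


def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        fmt = format_hint.lower()
    else:
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("wav", "csv"):
        raise FormatError(
            f"cannot determine format of {path} (expected .wav or .csv, "
            "or pass format_hint)"
        )
    return fmt


def read_signal(
    path: Union[str, Path],
    format_hint: Optional[str] = None,
    sample_rate_hz: Optional[float] = None,
) -> DopplerSignal:
    """Load a single-channel signal from WAV (mono PCM) or CSV.

    CSV files carry their rate in a ``# sample_rate_hz=<f>`` comment line;
    a file without one requires an explicit ``sample_rate_hz``.  Stereo or
    multi-channel WAV is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty signal file: {path}")
    fmt = _detect_format(path, format_hint)

    if fmt == "wav":
        try:
            rate, data = wavfile.read(path)
        except Exception as exc:
            raise FormatError(f"unreadable WAV file {path}: {exc}") from exc
        if data.ndim != 1:
            raise FormatError(
                f"{path} has {data.shape[1]} channels; only mono WAV is supported"
            )
        if np.issubdtype(data.dtype, np.integer):
            scale = float(np.iinfo(data.dtype).max)
            samples = data.astype(float) / scale
        else:
            samples = data.astype(float)
        return DopplerSignal(samples=samples, sample_rate_hz=float(rate))

    header_rate = None
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("sample_rate_hz"):
                    header_rate = float(body.split("=", 1)[1])
                continue
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise FormatError(f"bad sample line in {path}: {line!r}") from exc
    rate = header_rate if header_rate is not None else sample_rate_hz
    if rate is None:
        raise FormatError(
            f"{path} has no '# sample_rate_hz=' header and no rate was given"
        )
    if not samples:
        raise FormatError(f"no samples in {path}")
    return DopplerSignal(samples=np.array(samples), sample_rate_hz=float(rate))


def write_signal(
    signal: DopplerSignal,
    path: Union[str, Path],
    format_hint: Optional[str] = None,
) -> None:
    """Write a signal as 16-bit PCM mono WAV or as the flat CSV dialect.

    WAV output is peak-normalised to the 16-bit range; CSV stores full
    ``repr`` precision and round-trips exactly.
    """
    path = Path(path)
    fmt = _detect_format(path, format_hint)
    if fmt == "wav":
        peak = float(np.max(np.abs(signal.samples))) if len(signal.samples) else 0.0
        scale = 32767.0 / peak if peak > 0 else 0.0
        pcm = np.round(signal.samples * scale).astype(np.int16)
        wavfile.write(path, round(signal.sample_rate_hz), pcm)
    else:
        with open(path, "w") as fh:
            fh.write(f"# sample_rate_hz={signal.sample_rate_hz!r}\n")
            if signal.truth_bpm is not None:
                fh.write(f"# truth_bpm={signal.truth_bpm!r}\n")
            for s in signal.samples:
                fh.write(f"{float(s)!r}\n")


def generate_fixtures(out_dir: Union[str, Path], seed: int = 0) -> dict:
    """Write the standard fixture battery and return its manifest.

    Emits, under ``out_dir``:

    * ``doppler_hr<HR>_snr<SNR>.wav`` — simulated signals for every heart
      rate in :data:`FIXTURE_HEART_RATES_BPM` crossed with the SNRs in
      :data:`FIXTURE_SNRS_DB` (``inf`` = noiseless);
    * ``umbilical_type_{I,II,III}.csv`` — labelled umbilical traces;
    * ``birth_weight_summaries.csv``, ``general_conditions.csv``,
      ``av_anastomosis.csv`` — the reference cohort tables;
    * ``growth_reference_demo.csv`` — the synthetic growth-percentile table;
    * ``manifest.json`` — ground truth per file.

    Per-file noise seeds are derived deterministically from ``seed``; the
    same seed reproduces every file byte for byte.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out}: {exc}") from exc

    manifest: dict = {"seed": seed, "files": {}}

    for i, hr in enumerate(FIXTURE_HEART_RATES_BPM):
        for j, snr in enumerate(FIXTURE_SNRS_DB):
            cfg = DopplerConfig(
                heart_rate_bpm=hr,
                snr_db=snr,
                duration_s=FIXTURE_DURATION_S,
                seed=(seed * 1009 + i * 101 + j) % (2**31),
            )
            tag = "none" if np.isinf(snr) else f"{snr:g}"
            name = f"doppler_hr{hr:g}_snr{tag}.wav"
            write_signal(synthesize_doppler(cfg), out / name)
            manifest["files"][name] = {
                "kind": "doppler",
                "truth_bpm": hr,
                "snr_db": None if np.isinf(snr) else snr,
                "duration_s": FIXTURE_DURATION_S,
                "sample_rate_hz": cfg.sample_rate_hz,
            }

    for sfgr_type in ("I", "II", "III"):
        trace = synthesize_umbilical_trace(sfgr_type, seed=seed % (2**31))
        name = f"umbilical_type_{sfgr_type}.csv"
        sig = DopplerSignal(samples=trace, sample_rate_hz=100.0, truth_bpm=140.0)
        write_signal(sig, out / name)
        manifest["files"][name] = {
            "kind": "umbilical",
            "sfgr_type": sfgr_type,
            "heart_rate_bpm": 140.0,
            "sample_rate_hz": 100.0,
        }

    bw = pd.DataFrame(
        [
            ("sfgr", "larger", *_triple(cohortstats.BIRTH_WEIGHT_SFGR_LARGER)),
            ("sfgr", "smaller", *_triple(cohortstats.BIRTH_WEIGHT_SFGR_SMALLER)),
            ("control", "larger", *_triple(cohortstats.BIRTH_WEIGHT_CONTROL_LARGER)),
            ("control", "smaller", *_triple(cohortstats.BIRTH_WEIGHT_CONTROL_SMALLER)),
        ],
        columns=["group", "twin", "mean_g", "sd_g", "n"],
    )
    bw.to_csv(out / "birth_weight_summaries.csv", index=False)
    manifest["files"]["birth_weight_summaries.csv"] = {"kind": "summary_table"}

    gc = pd.DataFrame(
        [
            (k, a, 23, b, 32)
            for k, (a, b) in cohortstats.GENERAL_CONDITION_COUNTS.items()
        ],
        columns=["condition", "sfgr_count", "sfgr_n", "control_count", "control_n"],
    )
    gc.to_csv(out / "general_conditions.csv", index=False)
    manifest["files"]["general_conditions.csv"] = {"kind": "summary_table"}

    av = pd.DataFrame(
        [(g, c, n) for g, (c, n) in cohortstats.AV_ANASTOMOSIS_COUNTS.items()],
        columns=["group", "count", "n"],
    )
    av.to_csv(out / "av_anastomosis.csv", index=False)
    manifest["files"]["av_anastomosis.csv"] = {"kind": "summary_table"}

    GrowthReference.demo().to_csv(out / "growth_reference_demo.csv")
    manifest["files"]["growth_reference_demo.csv"] = {"kind": "growth_reference"}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _triple(s: cohortstats.SummaryStats):
    return (s.mean, s.sd, s.n)
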