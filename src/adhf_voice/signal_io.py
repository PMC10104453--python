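"""Recording I/O and preprocessing.

Recordings arrive from two sensors: an acoustic microphone (MIC, native
44,100 Hz) and a neck-surface accelerometer (ACC, native 11,025 Hz).  All
analysis runs at a common 25,000 Hz rate.  MIC signals are additionally
high-pass filtered at 70 Hz to remove low-frequency room noise, using the
Praat "pass Hann band" convention: the spectrum is multiplied by a
raised-cosine edge that is zero below ``cutoff - smoothing/2`` and one above
``cutoff + smoothing/2`` (20 and 120 Hz at the defaults).  Amplitude is never
normalized; the downstream spectral measures are level-robust.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

ANALYSIS_RATE = 25_000
HIGHPASS_CUTOFF_HZ = 70.0
HIGHPASS_SMOOTHING_HZ = 100.0


class Sensor(str, enum.Enum):
    MIC = "mic"
    ACC = "acc"


class Task(str, enum.Enum):
    VOWEL = "vowel"
    SENTENCES = "sentences"
    RAINBOW = "rainbow"
    PASSAGE2 = "passage2"
    SPONTANEOUS = "spontaneous"
    MPT = "mpt"


#: Tasks consisting of continuous speech, for which phrase measures apply.
CONTINUOUS_TASKS = (Task.SENTENCES, Task.RAINBOW, Task.PASSAGE2, Task.SPONTANEOUS)


@dataclass(frozen=True)
class Waveform:
    """A mono recording with its sample rate and sensor tag."""

    samples: np.ndarray
    rate: int
    sensor: Sensor = Sensor.MIC

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"expected mono samples, got shape {samples.shape}")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SessionManifest:
    """One row of the session manifest binding a file to its metadata."""

    participant_id: str
    day_index: int
    task: Task
    sensor: Sensor
    path: str
    repeat: int = 0

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError("day_index starts at 1 (admission day)")


def load_recording(path: str | Path, sensor: Sensor = Sensor.MIC) -> Waveform:
    """Read a mono PCM/float WAV file.

    Integer PCM is scaled to [-1, 1); float data is passed through unchanged.
    Multichannel files are rejected: the recording protocol produces one
    channel per sensor and silent downmixing would hide manifest errors.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, found {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV dtype {data.dtype}")
    return Waveform(samples=samples, rate=int(rate), sensor=sensor)


def save_recording(path: str | Path, w: Waveform) -> None:
    """Write a waveform as a float32 WAV (lossless for float32-valued data)."""
    wavfile.write(str(path), w.rate, w.samples.astype(np.float32))


def resample(w: Waveform, rate: int = ANALYSIS_RATE) -> Waveform:
    """Polyphase rational resampling to `rate`.

    The native rates (44,100 and 11,025 Hz) have exact rational ratios to
    25,000 Hz, so polyphase resampling introduces no cumulative drift.
    """
    if w.rate == rate:
        return w
    ratio = Fraction(rate, w.rate)
    samples = resample_poly(w.samples, ratio.numerator, ratio.denominator)
    return replace(w, samples=samples, rate=rate)


def hann_highpass(
    samples: np.ndarray,
    rate: int,
    cutoff: float = HIGHPASS_CUTOFF_HZ,
    smoothing: float = HIGHPASS_SMOOTHING_HZ,
) -> np.ndarray:
    """Zero-phase spectral high-pass with a raised-cosine (Hann) edge.

    The transfer function is 0 below ``cutoff - smoothing/2``, 1 above
    ``cutoff + smoothing/2``, and a raised cosine in between — the shape
    Praat applies for "Filter (pass Hann band)" with a high-pass band.
    """
    n = len(samples)
    if n == 0:
        return samples.copy()
    lo = cutoff - smoothing / 2.0
    hi = cutoff + smoothing / 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    weight = np.ones_like(freqs)
    weight[freqs <= lo] = 0.0
    edge = (freqs > lo) & (freqs < hi)
    weight[edge] = 0.5 - 0.5 * np.cos(np.pi * (freqs[edge] - lo) / (hi - lo))
    spectrum = np.fft.rfft(samples)
    return np.fft.irfft(spectrum * weight, n=n)


def preprocess(w: Waveform, highpass_acc: bool = False) -> Waveform:
    """Resample to the 25 kHz analysis rate and high-pass filter MIC signals.

    Parameters
    ----------
    w:
        Input waveform at its native rate.
    highpass_acc:
        Also high-pass filter accelerometer signals.  The protocol describes
        filtering only for the microphone channel, so this defaults to False.
    """
    out = resample(w, ANALYSIS_RATE)
    if w.sensor == Sensor.MIC or highpass_acc:
        filtered = hann_highpass(out.samples, out.rate)
        out = replace(out, samples=filtered)
    return out


# ---------------------------------------------------------------------------
# Manifest handling

_MANIFEST_COLUMNS = ["participant_id", "day_index", "task", "sensor", "repeat", "path"]


def read_manifest(path: str | Path) -> list[SessionManifest]:
    """Read a session manifest CSV.

    Expected columns: participant_id, day_index, task, sensor, repeat, path.
    The (participant, day, task, sensor, repeat) key must be unique.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    key_cols = ["participant_id", "day_index", "task", "sensor", "repeat"]
    if df.duplicated(subset=key_cols).any():
        raise ValueError("manifest contains duplicate (participant, day, task, sensor, repeat) keys")
    return [
        SessionManifest(
            participant_id=str(row.participant_id),
            day_index=int(row.day_index),
            task=Task(str(row.task).lower()),
            sensor=Sensor(str(row.sensor).lower()),
            repeat=int(row.repeat),
            path=str(row.path),
        )
        for row in df.itertuples(index=False)
    ]


def write_manifest(path: str | Path, entries: list[SessionManifest]) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "day_index": e.day_index,
                "task": e.task.value,
                "sensor": e.sensor.value,
                "repeat": e.repeat,
                "path": e.path,
            }
            for e in entries
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)
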