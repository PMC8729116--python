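"""WAV and label-track I/O for abdominal sound recordings.

Recordings are mono waveforms in [-1, 1] at a fixed sampling rate
(11025 Hz by default, the nearest standard rate to the ~11 kHz used by
clinical bowel-sound acquisition hardware).  Event annotations travel as
Audacity-style label tracks: plain text, one interval per line,
``start<TAB>end<TAB>label`` in decimal seconds.  All intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_SAMPLE_RATE = 11025

#: Labels that count as bowel sound (positive class) in a label track.
BS_LABELS = frozenset({"BS", "SB", "MB", "CRS", "HS"})
#: Labels that count as background / non bowel sound.
NON_BS_LABELS = frozenset({"non-BS", "noise"})


class Channel(str, enum.Enum):
    """Abdominal sensor placement site."""

    RLQ = "RLQ"  # right lower quadrant (ileocecal region)
    LUQ = "LUQ"  # left upper quadrant (stomach / transverse colon)
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Stereo files store RLQ on channel 0 and LUQ on channel 1 by convention.
_CHANNEL_INDEX = {Channel.RLQ: 0, Channel.LUQ: 1, Channel.UNKNOWN: 0}


@dataclass
class AudioRecording:
    """A mono waveform with its sampling rate and sensor channel tag."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    channel: Channel = Channel.UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioRecording samples must be finite")
        if isinstance(self.channel, str):
            self.channel = Channel(self.channel)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open interval [start_s, end_s)."""
        i0 = int(round(start_s * self.sample_rate))
        i1 = int(round(end_s * self.sample_rate))
        if self.samples.size < i1 <= self.samples.size + 1:
            i1 = self.samples.size  # float boundary rounding
        if i0 < 0 or i1 > self.samples.size:
            raise ValueError(
                f"slice [{start_s:.4f}, {end_s:.4f}) s outside recording of "
                f"{self.duration_s:.4f} s"
            )
        return self.samples[i0:i1]


@dataclass(frozen=True)
class LabelInterval:
    """A time-stamped ``[start_s, end_s)`` span with a text label.

    Used both for ground-truth annotations (labels ``BS``, ``non-BS`` or a
    subtype name ``SB``/``MB``/``CRS``/``HS``/``noise``) and for detector
    output.  Unknown labels are preserved verbatim.
    """

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}): "
                "need 0 <= start < end"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_bs(self) -> bool:
        return self.label in BS_LABELS


def read_wav(path: str | Path, channel: Channel | str = Channel.UNKNOWN) -> AudioRecording:
    """Read a RIFF/WAVE file into an :class:`AudioRecording`.

    16-bit PCM is scaled by 1/32768; 32-bit PCM by 1/2**31; 8-bit unsigned
    is re-centred; float WAV is taken as-is.  A multi-channel file is
    reduced to the channel conventionally associated with ``channel``
    (RLQ -> first, LUQ -> second).
    """
    path = Path(path)
    if isinstance(channel, str):
        channel = Channel(channel)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-WAV
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path} contains no audio")
    if data.ndim == 2:
        idx = min(_CHANNEL_INDEX[channel], data.shape[1] - 1)
        data = data[:, idx]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64 WAV
        samples = data.astype(np.float64)
    return AudioRecording(samples, sample_rate=int(rate), channel=channel)


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV (values clipped to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), rec.sample_rate, pcm)


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Band-limited resampling to ``target_rate`` (polyphase)."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.sample_rate:
        return AudioRecording(rec.samples.copy(), rec.sample_rate, rec.channel)
    ratio = Fraction(int(target_rate), int(rec.sample_rate))
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return AudioRecording(out, sample_rate=int(target_rate), channel=rec.channel)


def read_label_track(path: str | Path) -> list[LabelInterval]:
    """Parse an Audacity label track (``start<TAB>end<TAB>label`` lines).

    Intervals are returned sorted by start time.  Lines that are empty or
    whitespace-only are skipped; malformed lines raise with their line
    number.
    """
    intervals: list[LabelInterval] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'start<TAB>end<TAB>label', got {line!r}"
                )
            try:
                start_s = float(parts[0])
                end_s = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric time field") from exc
            if not math.isfinite(start_s) or not math.isfinite(end_s):
                raise ValueError(f"{path}:{lineno}: non-finite time field")
            if start_s >= end_s:
                raise ValueError(
                    f"{path}:{lineno}: start {start_s} must be < end {end_s}"
                )
            intervals.append(LabelInterval(start_s, end_s, parts[2]))
    intervals.sort(key=lambda iv: (iv.start_s, iv.end_s))
    return intervals


def write_label_track(events: Iterable, path: str | Path) -> None:
    """Write intervals/events as an Audacity label track (4 decimals).

    Accepts anything with ``start_s``/``end_s`` and either a ``label``
    attribute or not (defaults to ``BS``).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            label = getattr(ev, "label", "BS")
            fh.write(f"{ev.start_s:.4f}\t{ev.end_s:.4f}\t{label}\n")
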