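"""Acoustic features of detected bowel-sound events.

Four features drive the fasted/fed comparison:

* **duration_per_min** — total seconds of BS per minute of recording;
* **SC** (spectral centroid) — the amplitude-weighted mean frequency,
  the "centre of mass" of the event spectrum, in Hz;
* **SBW** (half-maximum spectral bandwidth) — the frequency extent over
  which the spectral amplitude is at least half its maximum, in Hz;
* **MCR** (mean-crossing ratio) — the number of times the waveform
  crosses its mean value, divided by the number of samples.

SC/SBW/MCR are computed per event and aggregated per recording with the
median (robust to the occasional long CRS); spectra are mean magnitude
spectra over 50 ms Hann frames with 5 ms shift.  Features are computed on
high-pass-filtered audio — the same preprocessing the detector sees — so
centroids exclude sub-80 Hz energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .audio_io import AudioRecording, Channel
from .features import PreprocessConfig

_FRAME_LEN_S = 0.050
_FRAME_SHIFT_S = 0.005


from functools import lru_cache


@lru_cache(maxsize=16)
def _hann(n: int) -> np.ndarray:
    return np.hanning(n)


@dataclass
class EventSpectrum:
    """Mean magnitude spectrum of one event on a uniform 0-Nyquist grid."""

    freqs_hz: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.freqs_hz.shape != self.amplitude.shape:
            raise ValueError("freqs_hz and amplitude must have the same shape")
        if np.any(self.amplitude < 0) or not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be non-negative and finite")


@dataclass
class RecordingFeatures:
    """Per-recording feature quadruple feeding the paired statistics.

    Spectral features are None (missing) when the recording has no events.
    """

    subject_id: str
    channel: Channel
    state: str
    duration_per_min: float           # s of BS per minute, in [0, 60]
    sc_hz: float | None               # median spectral centroid
    sbw_hz: float | None              # median half-max bandwidth
    mcr: float | None                 # median mean-crossing ratio
    n_events: int = 0


def _event_samples(rec: AudioRecording, event) -> np.ndarray:
    x = rec.slice(event.start_s, event.end_s)
    if x.size == 0:
        raise ValueError("empty event")
    return x


def event_spectrum(rec: AudioRecording, event) -> EventSpectrum:
    """Mean magnitude spectrum over Hann frames spanning the event.

    Events shorter than one 50 ms frame use a single zero-padded frame.
    """
    x = _event_samples(rec, event)
    fs = rec.sample_rate
    flen = int(round(_FRAME_LEN_S * fs))
    fshift = int(round(_FRAME_SHIFT_S * fs))
    n_fft = int(2 ** math.ceil(math.log2(flen)))
    if x.size < flen:
        frames = np.pad(x, (0, flen - x.size))[None, :]
    else:
        n_frames = (x.size - flen) // fshift + 1
        idx = np.arange(flen)[None, :] + fshift * np.arange(n_frames)[:, None]
        frames = x[idx]
    frames = (frames * _hann(flen)).astype(np.float32)
    mags = np.abs(np.fft.rfft(frames, n=n_fft, axis=1))
    return EventSpectrum(np.fft.rfftfreq(n_fft, d=1.0 / fs), mags.mean(axis=0))


def spectral_centroid(spec: EventSpectrum) -> float | None:
    """Amplitude-weighted mean frequency; None for an all-zero spectrum."""
    total = spec.amplitude.sum()
    if total <= 0:
        return None
    return float(np.dot(spec.freqs_hz, spec.amplitude) / total)


def spectral_bandwidth_halfmax(spec: EventSpectrum) -> float | None:
    """Extent of frequencies with amplitude >= half the maximum.

    Uses the total extent (lowest to highest qualifying grid frequency),
    not only the contiguous band around the peak.
    """
    peak = spec.amplitude.max()
    if peak <= 0:
        return None
    qual = np.flatnonzero(spec.amplitude >= 0.5 * peak)
    return float(spec.freqs_hz[qual[-1]] - spec.freqs_hz[qual[0]])


def mean_crossing_ratio(rec: AudioRecording, event) -> float:
    """Sign changes of (x - mean) per sample; exact zeros keep the
    previous nonzero sign so they never count as extra crossings."""
    x = _event_samples(rec, event)
    if x.size < 2:
        raise ValueError("event must contain at least 2 samples")
    d = x - x.mean()
    signs = np.sign(d)
    # zeros adopt the previous nonzero sign, which is equivalent to
    # dropping them before counting sign changes
    s = signs[signs != 0]
    crossings = int(np.sum(s[1:] != s[:-1]))
    return crossings / x.size


def recording_features(rec: AudioRecording, events: Sequence,
                       channel: Channel | str = Channel.UNKNOWN,
                       state: str = "", subject_id: str = "",
                       preprocessed: bool = True,
                       cfg: PreprocessConfig | None = None) -> RecordingFeatures:
    """Aggregate the four features over a recording's events.

    ``preprocessed=False`` applies the standard high-pass first.  With
    zero events the duration is 0 and the spectral features are missing.
    """
    from .features import highpass  # local import avoids cycle at module load

    if rec.duration_s <= 0:
        raise ValueError("recording duration must be positive")
    if isinstance(channel, str) and channel:
        channel = Channel(channel)
    if not preprocessed:
        rec = highpass(rec, cfg or PreprocessConfig())
    total_s = float(sum(ev.end_s - ev.start_s for ev in events))
    duration_per_min = total_s / (rec.duration_s / 60.0)
    scs, sbws, mcrs = [], [], []
    for ev in events:
        spec = event_spectrum(rec, ev)
        sc = spectral_centroid(spec)
        sbw = spectral_bandwidth_halfmax(spec)
        if sc is not None:
            scs.append(sc)
        if sbw is not None:
            sbws.append(sbw)
        mcrs.append(mean_crossing_ratio(rec, ev))
    return RecordingFeatures(
        subject_id=subject_id,
        channel=channel if isinstance(channel, Channel) else Channel.UNKNOWN,
        state=state,
        duration_per_min=duration_per_min,
        sc_hz=float(np.median(scs)) if scs else None,
        sbw_hz=float(np.median(sbws)) if sbws else None,
        mcr=float(np.median(mcrs)) if mcrs else None,
        n_events=len(events),
    )


def cohort_features(cohort, use_truth: bool = True,
                    detector=None, **detect_kw) -> list[RecordingFeatures]:
    """Per-recording features for a simulated cohort.

    With ``use_truth=True`` the simulator's ground-truth intervals serve
    as events (isolating the feature statistics from detector error);
    otherwise a trained detector is run on each recording.
    """
    from .segment import detect as run_detect

    out = []
    for rec in cohort:
        if use_truth:
            events = [iv for iv in rec.sim.truth if iv.is_bs]
        else:
            if detector is None:
                raise ValueError("detector required when use_truth=False")
            events = run_detect(detector, rec.sim.audio, **detect_kw)
        out.append(recording_features(rec.sim.audio, events,
                                      channel=rec.channel, state=rec.state,
                                      subject_id=rec.subject_id,
                                      preprocessed=False))
    return out
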