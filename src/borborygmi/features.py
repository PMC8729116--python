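"""Preprocessing and Mel-spectrogram featurization.

The detector operates on 60 ms slices of high-pass-filtered audio.  Each
slice is framed with a 50 ms window and 5 ms shift (hence exactly three
frames per slice), projected onto 128 triangular Mel filters spanning
0 Hz to Nyquist, converted to dB and min-max normalized per slice into
[0, 1].  The result is the 128x3 input tensor of the classifier.

The high-pass filter is a second-order Butterworth at 80 Hz, applied
forward-backward (zero phase) so event time stamps are not shifted; the
combined response is the squared single-pass magnitude.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, get_window, sosfiltfilt

from .audio_io import (
    AudioRecording,
    LabelInterval,
    BS_LABELS,
    NON_BS_LABELS,
    DEFAULT_SAMPLE_RATE,
)

logger = logging.getLogger(__name__)


@lru_cache(maxsize=32)
def _highpass_sos(order: int, cutoff_hz: float, nyq: float):
    return butter(order, cutoff_hz / nyq, btype="highpass", output="sos")

DB_FLOOR = 80.0  # dynamic range kept below the per-slice maximum, dB


@dataclass(frozen=True)
class PreprocessConfig:
    """Front-end geometry: filtering, framing and Mel resolution."""

    hp_order: int = 2
    hp_cutoff_hz: float = 80.0
    frame_len_s: float = 0.050
    frame_shift_s: float = 0.005
    n_mel: int = 128
    sample_len_s: float = 0.060

    def __post_init__(self) -> None:
        if self.sample_len_s < self.frame_len_s:
            raise ValueError("sample_len_s must be >= frame_len_s")

    @property
    def frames_per_sample(self) -> int:
        # epsilon guards against binary rounding of the 10 ms difference
        return int(np.floor((self.sample_len_s - self.frame_len_s)
                            / self.frame_shift_s + 1e-9)) + 1

    def frame_len_n(self, sample_rate: int) -> int:
        return int(round(self.frame_len_s * sample_rate))

    def frame_shift_n(self, sample_rate: int) -> int:
        return int(round(self.frame_shift_s * sample_rate))

    def sample_len_n(self, sample_rate: int) -> int:
        return (self.frame_len_n(sample_rate)
                + (self.frames_per_sample - 1) * self.frame_shift_n(sample_rate))

    def n_fft(self, sample_rate: int) -> int:
        return int(2 ** np.ceil(np.log2(self.frame_len_n(sample_rate))))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MelSample:
    """One normalized 128x3 Mel-spectrogram slice (the classifier input)."""

    values: np.ndarray           # (n_mel, n_frames), in [0, 1]
    origin_s: float = 0.0        # slice start time in the source recording
    label: str | None = None     # "BS" / "non-BS"
    subtype: str | None = None   # "SB"/"MB"/"CRS"/"HS" when known

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("MelSample values must be 2-D (n_mel x n_frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MelSample values must be finite")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("MelSample values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def highpass(rec: AudioRecording, cfg: PreprocessConfig | None = None) -> AudioRecording:
    """Zero-phase Butterworth high-pass (default: 2nd order, 80 Hz).

    Forward-backward application keeps events exactly aligned in time; the
    effective attenuation at the cutoff is therefore 6 dB (the square of
    the single-pass -3 dB).
    """
    cfg = cfg or PreprocessConfig()
    nyq = rec.sample_rate / 2.0
    if cfg.hp_cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cfg.hp_cutoff_hz} Hz >= Nyquist {nyq} Hz"
        )
    y = sosfiltfilt(_highpass_sos(cfg.hp_order, cfg.hp_cutoff_hz, nyq),
                    rec.samples)
    return AudioRecording(y, rec.sample_rate, rec.channel)


def butterworth_highpass_gain(f_hz: float, cutoff_hz: float = 80.0,
                              order: int = 2, passes: int = 1) -> float:
    """Closed-form magnitude response |H(f)| of the Butterworth high-pass.

    ``passes=2`` gives the zero-phase (forward-backward) response.
    """
    ratio = (cutoff_hz / f_hz) ** (2 * order)
    single = 1.0 / np.sqrt(1.0 + ratio)
    return single ** passes


# ---------------------------------------------------------------------------
# Mel filterbank and slice featurization
# ---------------------------------------------------------------------------

def hz_to_mel(f_hz):
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mel: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular Mel filterbank, ``(n_mel, n_fft//2 + 1)``, 0 Hz-Nyquist."""
    nyq = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(nyq), n_mel + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0.0, nyq, n_fft // 2 + 1)
    fb = np.zeros((n_mel, fft_freqs.size))
    for i in range(n_mel):
        f_lo, f_c, f_hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - f_lo) / max(f_c - f_lo, 1e-9)
        down = (f_hi - fft_freqs) / max(f_hi - f_c, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_band_of(freq_hz: float, n_mel: int, sample_rate: int) -> int:
    """Index of the Mel band whose centre is nearest ``freq_hz``."""
    nyq = sample_rate / 2.0
    centers = mel_to_hz(np.linspace(hz_to_mel(0.0), hz_to_mel(nyq), n_mel + 2))[1:-1]
    return int(np.argmin(np.abs(centers - freq_hz)))


class MelFrontend:
    """Caches window/filterbank for repeated slice featurization."""

    def __init__(self, cfg: PreprocessConfig, sample_rate: int):
        self.cfg = cfg
        self.sample_rate = sample_rate
        self.frame_len = cfg.frame_len_n(sample_rate)
        self.frame_shift = cfg.frame_shift_n(sample_rate)
        self.slice_len = cfg.sample_len_n(sample_rate)
        self.n_fft = cfg.n_fft(sample_rate)
        self.window = get_window("hann", self.frame_len, fftbins=True)
        self.fb = mel_filterbank(cfg.n_mel, self.n_fft, sample_rate)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Normalized (n_mel, n_frames) Mel grid for one slice of samples."""
        if x.size < self.slice_len:
            raise ValueError(
                f"slice has {x.size} samples, need {self.slice_len}"
            )
        x = x[: self.slice_len]
        n_frames = self.cfg.frames_per_sample
        frames = np.stack([
            x[i * self.frame_shift: i * self.frame_shift + self.frame_len]
            for i in range(n_frames)
        ])
        spec = np.abs(np.fft.rfft(frames * self.window, n=self.n_fft, axis=1)) ** 2
        mel = self.fb @ spec.T  # (n_mel, n_frames)
        ref = mel.max()
        if ref <= 0:
            return np.zeros_like(mel)
        db = 10.0 * np.log10(np.maximum(mel, ref * 10.0 ** (-DB_FLOOR / 10.0)) / ref)
        lo, hi = db.min(), db.max()
        if hi - lo < 1e-12:  # constant slice: degenerate normalization
            return np.zeros_like(db)
        return (db - lo) / (hi - lo)


def mel_sample(rec: AudioRecording, start_s: float,
               cfg: PreprocessConfig | None = None,
               frontend: MelFrontend | None = None) -> MelSample:
    """Featurize the 60 ms slice starting at ``start_s``."""
    cfg = cfg or PreprocessConfig()
    fe = frontend or MelFrontend(cfg, rec.sample_rate)
    i0 = int(round(start_s * rec.sample_rate))
    if i0 < 0 or i0 + fe.slice_len > rec.samples.size:
        raise ValueError(
            f"slice at {start_s:.4f} s extends past recording of "
            f"{rec.duration_s:.4f} s"
        )
    values = fe(rec.samples[i0: i0 + fe.slice_len])
    return MelSample(values, origin_s=i0 / rec.sample_rate)


# ---------------------------------------------------------------------------
# dataset construction from labelled recordings
# ---------------------------------------------------------------------------

@dataclass
class MelDataset:
    """Array bundle of labelled Mel samples (classifier training data)."""

    X: np.ndarray               # (n, n_mel, n_frames)
    y: np.ndarray               # (n,) 1 = BS, 0 = non-BS
    subtype: np.ndarray         # (n,) unicode, "" when unknown
    origin_s: np.ndarray        # (n,) slice start times
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "MelDataset":
        return MelDataset(self.X[idx], self.y[idx], self.subtype[idx],
                          self.origin_s[idx], self.config)

    def save(self, path) -> None:
        np.savez_compressed(path, X=self.X, y=self.y, subtype=self.subtype,
                            origin_s=self.origin_s)

    @classmethod
    def load(cls, path, config: PreprocessConfig | None = None) -> "MelDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["X"], z["y"], z["subtype"], z["origin_s"],
                       config or PreprocessConfig())


def _interval_slices(iv: LabelInterval, rec_duration_s: float,
                     slice_len_s: float) -> list[float]:
    """Start times of the 60 ms slices taken from one labelled interval.

    Long intervals yield consecutive non-overlapping slices (remainder
    dropped); short intervals yield one slice centred on the interval
    midpoint, using surrounding context.
    """
    if iv.duration_s >= slice_len_s:
        n = int(np.floor(iv.duration_s / slice_len_s))
        return [iv.start_s + k * slice_len_s for k in range(n)]
    mid = 0.5 * (iv.start_s + iv.end_s)
    start = mid - slice_len_s / 2.0
    if start < 0.0 or start + slice_len_s > rec_duration_s:
        return []
    return [start]


def slice_dataset(recs: Sequence[tuple[AudioRecording, Sequence[LabelInterval]]],
                  cfg: PreprocessConfig | None = None,
                  seed: int | None = None,
                  balance: bool = False,
                  apply_highpass: bool = True) -> MelDataset:
    """Build a labelled Mel-sample dataset from recordings + label tracks.

    Intervals labelled with a BS subtype (or plain ``BS``) become positive
    samples tagged with their subtype; ``noise``/``non-BS`` intervals
    become negatives.  Intervals too close to a recording edge for a
    centred window are skipped with a warning.  With ``balance=True`` the
    majority class is randomly down-sampled (seeded) to the minority size.
    """
    cfg = cfg or PreprocessConfig()
    X, y, subtype, origin = [], [], [], []
    n_skipped = 0
    for rec, labels in recs:
        proc = highpass(rec, cfg) if apply_highpass else rec
        fe = MelFrontend(cfg, proc.sample_rate)
        for iv in labels:
            if iv.duration_s < 0.010:
                continue
            if iv.is_bs:
                lab, sub = 1, (iv.label if iv.label in BS_LABELS - {"BS"} else "")
            elif iv.label in NON_BS_LABELS:
                lab, sub = 0, ""
            else:
                continue
            starts = _interval_slices(iv, proc.duration_s, cfg.sample_len_s)
            if not starts:
                n_skipped += 1
                continue
            for s in starts:
                i0 = int(round(s * proc.sample_rate))
                if i0 < 0 or i0 + fe.slice_len > proc.samples.size:
                    n_skipped += 1
                    continue
                X.append(fe(proc.samples[i0: i0 + fe.slice_len]))
                y.append(lab)
                subtype.append(sub)
                origin.append(s)
    if n_skipped:
        logger.warning("slice_dataset: skipped %d interval slices at recording edges",
                       n_skipped)
    if not X:
        shp = (0, cfg.n_mel, cfg.frames_per_sample)
        return MelDataset(np.zeros(shp), np.zeros(0, dtype=int),
                          np.zeros(0, dtype="U4"), np.zeros(0), cfg)
    ds = MelDataset(np.stack(X), np.asarray(y, dtype=int),
                    np.asarray(subtype, dtype="U4"), np.asarray(origin), cfg)
    if balance:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(ds.y == 1)
        neg = np.flatnonzero(ds.y == 0)
        m = min(pos.size, neg.size)
        keep = np.sort(np.concatenate([
            rng.choice(pos, m, replace=False),
            rng.choice(neg, m, replace=False),
        ]))
        ds = ds.subset(keep)
    return ds


def noise_gap_labels(truth: Sequence[LabelInterval], duration_s: float,
                     margin_s: float = 0.08,
                     min_len_s: float = 0.06) -> list[LabelInterval]:
    """Label the event-free gaps of a recording as ``noise`` intervals.

    Used to harvest negative training samples from simulated recordings,
    keeping a safety margin around every true event.
    """
    out: list[LabelInterval] = []
    cursor = 0.0
    for iv in sorted(truth, key=lambda v: v.start_s):
        gap_end = iv.start_s - margin_s
        if gap_end - cursor >= min_len_s:
            out.append(LabelInterval(cursor, gap_end, "noise"))
        cursor = max(cursor, iv.end_s + margin_s)
    if duration_s - cursor >= min_len_s:
        out.append(LabelInterval(cursor, duration_s, "noise"))
    return out
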