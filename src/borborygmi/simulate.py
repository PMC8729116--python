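"""Synthetic abdominal-recording generator with ground-truth labels.

Real bowel-sound (BS) corpora are rarely shared, so every stage of the
pipeline is exercised on simulated recordings that emulate the four BS
subtypes seen on abdominal auscultation:

* **SB** (single burst): one short band-limited pulse, ~20-40 ms, with no
  other BS within 100 ms on either side.
* **MB** (multiple bursts): a cluster of 2-8 SB-like bursts separated by
  10-100 ms silent gaps, with burst-to-burst amplitude variation.
* **CRS** (continuous random sound): band-limited noise with a random
  amplitude envelope, 0.2-1.6 s, no rhythmic structure.
* **HS** (harmonic sound): a whistling-like stack of 1-12 harmonics on a
  200-800 Hz fundamental, all components kept below 4 kHz, optionally
  frequency-swept.

Events ride on a pink (1/f-shaped) background so that the classifier must
learn spectral *shape*, not loudness: BS spectrograms are spiky, noise
spectrograms are flat.  Event arrivals follow a homogeneous Poisson
process with rejection of overlaps; a 100 ms guard gap between any two
events preserves the SB isolation rule.  Fasted/fed condition shifts are
expressed as an event-rate factor, a spectral-centroid shift and a
bandwidth scale, which the downstream statistics should recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .audio_io import AudioRecording, Channel, LabelInterval, DEFAULT_SAMPLE_RATE

SUBTYPES = ("SB", "MB", "CRS", "HS")

#: Hard bounds on any labelled BS segment duration (seconds).
DURATION_BOUNDS_S = (0.02, 1.6)
#: Minimum silent gap enforced between any two placed events (seconds);
#: also guarantees the SB isolation rule (no BS within 100 ms of an SB).
MIN_EVENT_GAP_S = 0.100
#: Hard ceiling on harmonic-sound component frequencies (Hz).
HS_MAX_FREQ_HZ = 4000.0


@dataclass
class SubtypeParams:
    """Morphology parameters for one BS subtype.

    Frequencies are in Hz, durations in seconds, amplitudes are peak
    values relative to digital full scale.
    """

    kind: str
    duration_range_s: tuple[float, float]
    center_freq_range_hz: tuple[float, float]
    amplitude_range: tuple[float, float] = (0.05, 0.30)
    bandwidth_range_hz: tuple[float, float] = (150.0, 350.0)
    # MB only
    burst_count_range: tuple[int, int] = (2, 8)
    intra_gap_range_s: tuple[float, float] = (0.010, 0.100)
    # HS only
    n_harmonics_range: tuple[int, int] = (1, 12)
    sweep_rate_hz_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SUBTYPES:
            raise ValueError(f"unknown subtype kind {self.kind!r}")
        for name in ("duration_range_s", "center_freq_range_hz", "amplitude_range",
                     "bandwidth_range_hz", "intra_gap_range_s"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name}: min {lo} > max {hi}")
        lo, hi = self.duration_range_s
        if lo < DURATION_BOUNDS_S[0] or hi > DURATION_BOUNDS_S[1]:
            raise ValueError(
                f"duration_range_s {self.duration_range_s} outside {DURATION_BOUNDS_S}"
            )
        if not (1 <= self.n_harmonics_range[0] <= self.n_harmonics_range[1] <= 12):
            raise ValueError("n_harmonics_range must lie within [1, 12]")


def default_subtype_params() -> dict[str, SubtypeParams]:
    """Per-subtype morphology defaults.

    Centre frequencies sit in the few-hundred-Hz band where abdominal
    sounds concentrate; single bursts last 20-40 ms, harmonic sounds use
    fundamentals of 200-800 Hz.
    """
    return {
        "SB": SubtypeParams("SB", (0.020, 0.040), (300.0, 550.0)),
        "MB": SubtypeParams("MB", (0.070, 0.700), (300.0, 550.0)),
        "CRS": SubtypeParams("CRS", (0.200, 1.600), (300.0, 550.0)),
        "HS": SubtypeParams("HS", (0.100, 0.800), (200.0, 800.0),
                            sweep_rate_hz_per_s=400.0),
    }


@dataclass
class ConditionConfig:
    """Generative parameters for one physiological state (fasted or fed)."""

    state: str = "fasted"
    events_per_minute: float = 40.0
    subtype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SB": 0.55, "MB": 0.25, "CRS": 0.12, "HS": 0.08}
    )
    sc_shift_hz: float = 0.0      # additive shift of event centre frequencies
    sbw_scale: float = 1.0        # multiplicative scale of event bandwidths
    freq_scale: float = 1.0       # multiplicative jitter (subject random effect)
    noise_floor_db: float = -45.0  # background RMS, dB re full scale
    subtype_params: Mapping[str, SubtypeParams] = field(
        default_factory=default_subtype_params
    )

    def __post_init__(self) -> None:
        if self.events_per_minute < 0:
            raise ValueError("events_per_minute must be >= 0")
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix must sum to 1, got {total}")
        for k in self.subtype_mix:
            if k not in SUBTYPES:
                raise ValueError(f"unknown subtype {k!r} in subtype_mix")

    def replace(self, **kw) -> "ConditionConfig":
        return dataclasses.replace(self, **kw)


def detector_training_condition(**overrides) -> ConditionConfig:
    """Condition used to build classifier training corpora.

    The abundance ordering SB > MB > CRS > HS is kept, but the rarer
    subtypes are over-represented relative to a natural recording so the
    classifier sees enough of each morphology (the cohort analyses use
    the natural mix).
    """
    overrides.setdefault("subtype_mix",
                         {"SB": 0.40, "MB": 0.30, "CRS": 0.18, "HS": 0.12})
    return ConditionConfig(state="fasted", **overrides)


def fasted_condition(**overrides) -> ConditionConfig:
    """Default fasted-state configuration."""
    return ConditionConfig(state="fasted", **overrides)


def fed_condition(base: ConditionConfig | None = None,
                  duration_factor: float = 1.6,
                  sbw_scale: float = 0.85,
                  sc_shift_hz: float = 0.0) -> ConditionConfig:
    """Fed-state configuration derived from a fasted baseline.

    After food intake the total BS duration per minute rises (here via the
    event rate) and the spectral energy spread narrows (bandwidth scale
    < 1); the mean-crossing ratio is left untouched.
    """
    base = base or fasted_condition()
    return base.replace(
        state="fed",
        events_per_minute=base.events_per_minute * duration_factor,
        sbw_scale=base.sbw_scale * sbw_scale,
        sc_shift_hz=base.sc_shift_hz + sc_shift_hz,
    )


@dataclass
class SimRecording:
    """A simulated recording plus its ground-truth event labels."""

    audio: AudioRecording
    truth: list[LabelInterval]
    condition: ConditionConfig
    seed: int

    def __post_init__(self) -> None:
        dur = self.audio.duration_s
        for iv in self.truth:
            if iv.start_s < 0 or iv.end_s > dur + 1e-9:
                raise ValueError(f"truth interval {iv} outside [0, {dur:.3f}]")


# ---------------------------------------------------------------------------
# event waveform synthesis
# ---------------------------------------------------------------------------

def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


_FWHM_TO_SIGMA = 2.3548200450309493  # full width at half maximum of a Gaussian


def _band_noise(n: int, fc: float, bw: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Noise with a Gaussian band magnitude centred at ``fc``.

    The magnitude's full width at half maximum equals ``bw``, so the
    realized half-max spectral bandwidth tracks the configured value and
    the spectral centroid tracks ``fc`` (no heavy filter skirts).
    """
    white = rng.standard_normal(n, dtype=np.float32)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = max(bw, 10.0) / _FWHM_TO_SIGMA
    h = np.exp(-0.5 * ((f - fc) / sigma) ** 2).astype(np.float32)
    return np.fft.irfft(np.fft.rfft(white) * h, n)


def _smooth_noise(n: int, cutoff_hz: float, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Slowly varying random curve (low-passed white noise)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    h = np.exp(-0.5 * (f / cutoff_hz) ** 2).astype(np.float32)
    return np.fft.irfft(np.fft.rfft(rng.standard_normal(n, dtype=np.float32)) * h, n)


def _burst(duration_s: float, fc: float, bw: float, fs: float,
           rng: np.random.Generator) -> np.ndarray:
    """One band-limited pulse with fast attack and exponential decay."""
    n = max(int(round(duration_s * fs)), 8)
    x = _band_noise(n, fc, bw, fs, rng)
    t = np.arange(n) / fs
    tau = duration_s / 4.0
    env = (t / (0.15 * duration_s + 1e-12)).clip(max=1.0) * np.exp(-t / tau)
    x = x * env
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _crs(duration_s: float, fc: float, bw: float, fs: float,
         rng: np.random.Generator) -> np.ndarray:
    """Continuous band-limited noise with a slowly varying random envelope."""
    n = int(round(duration_s * fs))
    x = _band_noise(n, fc, bw, fs, rng)
    # random envelope: heavily smoothed rectified noise, floored so the
    # sound stays continuous rather than breaking into bursts
    env = np.abs(_smooth_noise(n, 8.0, fs, rng))
    env = 0.35 + 0.65 * env / (env.max() + 1e-12)
    # soft edges (5 ms ramps)
    ramp = min(int(0.005 * fs), n // 4)
    if ramp > 0:
        win = np.ones(n)
        win[:ramp] = np.linspace(0.0, 1.0, ramp)
        win[-ramp:] = np.linspace(1.0, 0.0, ramp)
        env = env * win
    x = x * env
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _harmonic(duration_s: float, f0: float, n_harmonics: int, sweep: float,
              fs: float, rng: np.random.Generator) -> np.ndarray:
    """Whistling-like harmonic stack, all components kept below 4 kHz."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # limit the sweep so the top harmonic never exceeds the 4 kHz ceiling
    ks = [k for k in range(1, n_harmonics + 1) if k * f0 <= HS_MAX_FREQ_HZ - 50.0]
    if not ks:
        ks = [1]
    kmax = ks[-1]
    max_sweep = (HS_MAX_FREQ_HZ - 50.0 - kmax * f0) / (kmax * duration_s + 1e-12)
    sweep = float(np.clip(sweep, -f0 * 0.8 / duration_s, max_sweep))
    x = np.zeros(n)
    for k in ks:
        amp = 1.0 / k ** rng.uniform(0.5, 1.2)
        phase = 2 * np.pi * (k * f0 * t + 0.5 * k * sweep * t ** 2)
        x += amp * np.cos(phase + rng.uniform(0, 2 * np.pi))
    # smooth attack/release envelope (10% Tukey-like ramps)
    ramp = max(int(0.1 * n), 1)
    env = np.ones(n)
    env[:ramp] = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
    env[-ramp:] = env[:ramp][::-1]
    x = x * env
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def synth_event(params: SubtypeParams, sample_rate: int = DEFAULT_SAMPLE_RATE,
                rng_seed=0) -> tuple[np.ndarray, float]:
    """Synthesize one event waveform; returns ``(waveform, duration_s)``.

    The waveform's peak amplitude is drawn from ``params.amplitude_range``.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    rng = _as_rng(rng_seed)
    fc = rng.uniform(*params.center_freq_range_hz)
    bw = rng.uniform(*params.bandwidth_range_hz)
    amp = rng.uniform(*params.amplitude_range)

    if params.kind == "SB":
        dur = rng.uniform(*params.duration_range_s)
        x = _burst(dur, fc, bw, sample_rate, rng)
    elif params.kind == "MB":
        n_bursts = int(rng.integers(params.burst_count_range[0],
                                    params.burst_count_range[1] + 1))
        pieces: list[np.ndarray] = []
        total = 0.0
        for i in range(n_bursts):
            bdur = rng.uniform(0.020, 0.040)
            if i > 0:
                gap = rng.uniform(*params.intra_gap_range_s)
                if total + gap + bdur > DURATION_BOUNDS_S[1]:
                    break
                pieces.append(np.zeros(int(round(gap * sample_rate))))
                total += gap
            rel = rng.uniform(0.4, 1.0)  # burst-to-burst amplitude variation
            pieces.append(rel * _burst(bdur, fc * rng.uniform(0.9, 1.1),
                                       bw, sample_rate, rng))
            total += bdur
        x = np.concatenate(pieces)
        peak = np.max(np.abs(x))
        x = x / peak if peak > 0 else x
    elif params.kind == "CRS":
        dur = rng.uniform(*params.duration_range_s)
        x = _crs(dur, fc, bw, sample_rate, rng)
    elif params.kind == "HS":
        dur = rng.uniform(*params.duration_range_s)
        n_h = int(rng.integers(params.n_harmonics_range[0],
                               params.n_harmonics_range[1] + 1))
        f0 = min(fc, HS_MAX_FREQ_HZ - 100.0)
        sweep = rng.uniform(-1.0, 1.0) * params.sweep_rate_hz_per_s
        x = _harmonic(dur, f0, n_h, sweep, sample_rate, rng)
    else:  # pragma: no cover - guarded in SubtypeParams
        raise ValueError(params.kind)

    x = x * amp
    duration_s = x.size / sample_rate
    return x, duration_s


# ---------------------------------------------------------------------------
# background noise and full recordings
# ---------------------------------------------------------------------------

# classic 3-pole pink-noise shaping filter (Paul Kellet's economy form)
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f-shaped) noise of length ``n``."""
    white = rng.standard_normal(n + 2000, dtype=np.float32)
    x = lfilter(_PINK_B.astype(np.float32), _PINK_A.astype(np.float32),
                white)[2000:]
    rms = np.sqrt(np.mean(np.square(x, dtype=np.float64)))
    return x / np.float32(rms + 1e-12)


def _adjusted_params(base: SubtypeParams, cond: ConditionConfig) -> SubtypeParams:
    """Apply condition-level spectral shifts to subtype morphology."""
    f = cond.freq_scale
    lo, hi = base.center_freq_range_hz
    new_fc = (max(lo * f + cond.sc_shift_hz, 100.0),
              max(hi * f + cond.sc_shift_hz, 120.0))
    blo, bhi = base.bandwidth_range_hz
    new_bw = (max(blo * cond.sbw_scale, 20.0), max(bhi * cond.sbw_scale, 25.0))
    return dataclasses.replace(base, center_freq_range_hz=new_fc,
                               bandwidth_range_hz=new_bw)


def _place_in_free(free: list[tuple[float, float]], ev_dur: float,
                   rng: np.random.Generator) -> float | None:
    """Uniformly sample a start among all positions where the event fits,
    then carve the occupied span (plus guard gap) out of the free list."""
    feas = [max(0.0, (e - s) - ev_dur) for s, e in free]
    total = sum(feas)
    if total <= 0:
        return None
    x = rng.uniform(0.0, total)
    for (s, e), length in zip(list(free), feas):
        if x <= length:
            start = s + x
            idx = free.index((s, e))
            free.pop(idx)
            lo, hi = start - MIN_EVENT_GAP_S, start + ev_dur + MIN_EVENT_GAP_S
            if lo - s > 1e-9:
                free.insert(idx, (s, lo))
                idx += 1
            if e - hi > 1e-9:
                free.insert(idx, (hi, e))
            return start
        x -= length
    return None  # pragma: no cover - float edge


def generate_recording(duration_s: float, condition: ConditionConfig,
                       sample_rate: int = DEFAULT_SAMPLE_RATE,
                       seed: int = 0,
                       channel: Channel = Channel.UNKNOWN) -> SimRecording:
    """Generate one recording: pink background + Poisson event arrivals.

    The Poisson-drawn events are placed uniformly over the positions
    still free, longest first; events never overlap and keep a 100 ms
    guard gap from each other.  If an event no longer fits anywhere the
    requested density is infeasible and an error reports the density
    achieved.  Deterministic given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    audio = pink_noise(n, rng) * 10.0 ** (condition.noise_floor_db / 20.0)

    n_events = rng.poisson(condition.events_per_minute * duration_s / 60.0)
    kinds = list(condition.subtype_mix.keys())
    probs = np.array([condition.subtype_mix[k] for k in kinds], dtype=float)
    waves = []
    for _ in range(n_events):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        params = _adjusted_params(condition.subtype_params[kind], condition)
        wave, ev_dur = synth_event(params, sample_rate, rng)
        if ev_dur < duration_s:
            waves.append((kind, wave, ev_dur))
    # place longest first so long CRS events are not squeezed out
    truth: list[LabelInterval] = []
    free: list[tuple[float, float]] = [(0.0, duration_s)]
    for kind, wave, ev_dur in sorted(waves, key=lambda t: -t[2]):
        start = _place_in_free(free, ev_dur, rng)
        if start is None:
            achieved = 60.0 * len(truth) / duration_s
            raise RuntimeError(
                f"event placement failed: requested "
                f"{condition.events_per_minute:.1f}/min, achieved "
                f"{achieved:.1f}/min in {duration_s:.0f} s"
            )
        i0 = int(round(start * sample_rate))
        audio[i0:i0 + wave.size] += wave
        truth.append(LabelInterval(i0 / sample_rate,
                                   i0 / sample_rate + wave.size / sample_rate,
                                   kind))
    truth.sort(key=lambda iv: iv.start_s)
    rec = AudioRecording(audio, sample_rate=sample_rate, channel=channel)
    return SimRecording(rec, truth, condition, seed)


def training_corpus(total_duration_s: float,
                    condition: ConditionConfig | None = None,
                    sample_rate: int = DEFAULT_SAMPLE_RATE,
                    seed: int = 0,
                    chunk_s: float = 120.0) -> list[tuple[AudioRecording, list[LabelInterval]]]:
    """Simulated recordings with BS-subtype and noise labels, ready for
    dataset slicing.

    Generates ``total_duration_s`` of audio in chunks; each chunk's label
    track contains the true events (subtype-labelled) plus the event-free
    gaps labelled ``noise``, so both classes can be harvested.
    """
    from .features import noise_gap_labels  # lazy: features imports audio_io only

    condition = condition or ConditionConfig()
    rng = np.random.default_rng(seed)
    out = []
    remaining = total_duration_s
    while remaining > 1.0:
        dur = min(chunk_s, remaining)
        sim = generate_recording(dur, condition, sample_rate,
                                 int(rng.integers(0, 2 ** 31 - 1)))
        labels = list(sim.truth) + noise_gap_labels(sim.truth, sim.audio.duration_s)
        out.append((sim.audio, sorted(labels, key=lambda iv: iv.start_s)))
        remaining -= dur
    return out


@dataclass
class CohortRecording:
    """One recording of a simulated subject (subject x channel x state)."""

    subject_id: str
    channel: Channel
    state: str
    sim: SimRecording


def generate_cohort(n_subjects: int,
                    fasted_cfg: ConditionConfig,
                    fed_cfg: ConditionConfig,
                    per_state_duration_s: float = 60.0,
                    sample_rate: int = DEFAULT_SAMPLE_RATE,
                    seed: int = 0,
                    subject_rate_sd: float = 0.12,
                    subject_freq_sd: float = 0.05) -> list[CohortRecording]:
    """Simulate a paired cohort: per subject, RLQ+LUQ in both states.

    Subject-level random effects (log-normal event-rate multiplier,
    centre-frequency jitter) are shared across that subject's four
    recordings, so fasted/fed contrasts are paired within subject.  The
    LUQ channel runs at a slightly lower event rate than RLQ, mimicking
    site-dependent activity.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(seed)
    out: list[CohortRecording] = []
    channel_rate = {Channel.RLQ: 1.0, Channel.LUQ: 0.8}
    for i in range(n_subjects):
        rate_mult = float(np.exp(master.normal(0.0, subject_rate_sd)))
        freq_mult = float(np.exp(master.normal(0.0, subject_freq_sd)))
        sid = f"S{i + 1:02d}"
        for channel in (Channel.RLQ, Channel.LUQ):
            for cfg in (fasted_cfg, fed_cfg):
                rec_seed = int(master.integers(0, 2 ** 31 - 1))
                cfg_i = cfg.replace(
                    events_per_minute=cfg.events_per_minute * rate_mult
                    * channel_rate[channel],
                    freq_scale=cfg.freq_scale * freq_mult,
                )
                sim = generate_recording(per_state_duration_s, cfg_i,
                                         sample_rate, rec_seed, channel)
                out.append(CohortRecording(sid, channel, cfg.state, sim))
    return out
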