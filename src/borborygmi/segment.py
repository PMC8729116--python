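"""From per-window predictions to time-stamped bowel-sound events.

The trained classifier is swept across a recording with a moving window
(50 ms hop by default).  Runs of at least three adjacent BS-predicted
windows become candidate events: the start is the first BS window of the
run, the end is the start of the first following non-BS window (or the
last window start plus one hop at the track end).  Candidates within
100 ms of each other are merged into one event — the quiet stretches
between them are kept as inter-burst intervals (``burst_spans``).

With the default 50 ms hop the >=3-window rule implies a minimum
detectable span of ~150 ms; to resolve 20-40 ms single bursts, sweep
with a smaller hop (e.g. 5 ms) — both ``hop_s`` and ``min_run`` are
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audio_io import AudioRecording, LabelInterval
from .detector import BSDetector
from .features import MelFrontend, PreprocessConfig, highpass

DEFAULT_HOP_S = 0.050
DEFAULT_MIN_RUN = 3
DEFAULT_MERGE_GAP_S = 0.100


@dataclass
class PredictionTrack:
    """Binary BS/non-BS decisions on a uniform window grid."""

    window_starts_s: np.ndarray
    labels: np.ndarray            # 1 = BS, 0 = non-BS
    hop_s: float = DEFAULT_HOP_S
    window_len_s: float = 0.060
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.window_starts_s = np.asarray(self.window_starts_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.window_starts_s.size != self.labels.size:
            raise ValueError("window_starts_s and labels must match in length")
        if self.window_starts_s.size > 1:
            diffs = np.diff(self.window_starts_s)
            if not np.allclose(diffs, self.hop_s, atol=1e-9):
                raise ValueError("window starts must advance by exactly hop_s")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class BowelSoundEvent:
    """A post-merge detected event with its constituent burst spans."""

    start_s: float
    end_s: float
    burst_spans: list[tuple[float, float]] = field(default_factory=list)
    n_windows: int = 0
    label: str = "BS"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"event start {self.start_s} must be < end {self.end_s}")
        prev_end = None
        for s, e in self.burst_spans:
            if s < self.start_s - 1e-9 or e > self.end_s + 1e-9 or s >= e:
                raise ValueError(f"burst span ({s}, {e}) outside event")
            if prev_end is not None and s < prev_end - 1e-9:
                raise ValueError("burst spans must be sorted and non-overlapping")
            prev_end = e

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def sweep(model: BSDetector, rec: AudioRecording,
          hop_s: float = DEFAULT_HOP_S,
          window_len_s: float | None = None,
          apply_highpass: bool = True,
          batch_size: int = 512) -> PredictionTrack:
    """Classify every window at 0, hop, 2*hop, ... while the window fits."""
    pre = model.pre
    window_len_s = window_len_s if window_len_s is not None else pre.sample_len_s
    if rec.duration_s < window_len_s:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than one "
            f"{window_len_s:.3f} s window"
        )
    proc = highpass(rec, pre) if apply_highpass else rec
    fe = MelFrontend(pre, proc.sample_rate)
    # epsilon guards the exact-fit case against binary rounding
    n_windows = int(np.floor((rec.duration_s - window_len_s) / hop_s + 1e-9)) + 1
    starts = np.arange(n_windows) * hop_s
    X = np.empty((n_windows, pre.n_mel, pre.frames_per_sample))
    for i, s in enumerate(starts):
        i0 = int(round(s * proc.sample_rate))
        i0 = min(i0, proc.samples.size - fe.slice_len)
        X[i] = fe(proc.samples[i0:i0 + fe.slice_len])
    probs, labels = model.predict(X, batch_size=batch_size)
    return PredictionTrack(starts, labels, hop_s=hop_s,
                           window_len_s=window_len_s, probabilities=probs)


def runs_to_candidates(track: PredictionTrack,
                       min_run: int = DEFAULT_MIN_RUN) -> list[tuple[float, float]]:
    """Maximal runs of >= ``min_run`` adjacent BS windows as (start, end).

    Candidate start = first window start of the run; candidate end = start
    of the first non-BS window after the run, or last window start + hop
    when the run touches the end of the track.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    labels = track.labels
    starts = track.window_starts_s
    out: list[tuple[float, float]] = []
    i = 0
    n = labels.size
    while i < n:
        if labels[i] == 1:
            j = i
            while j < n and labels[j] == 1:
                j += 1
            if j - i >= min_run:
                start = float(starts[i])
                end = float(starts[j]) if j < n else float(starts[n - 1] + track.hop_s)
                out.append((start, end))
            i = j
        else:
            i += 1
    return out


def merge_events(candidates: Sequence[tuple[float, float]],
                 merge_gap_s: float = DEFAULT_MERGE_GAP_S) -> list[BowelSoundEvent]:
    """Coalesce candidates whose inter-gap is <= ``merge_gap_s`` (inclusive).

    Merging is transitive; the merged event spans from the first
    candidate's start to the last one's end, and the original candidate
    spans are kept as ``burst_spans``.
    """
    cands = list(candidates)
    for k in range(len(cands) - 1):
        if cands[k][1] > cands[k + 1][0] + 1e-12 or cands[k][0] > cands[k + 1][0]:
            raise ValueError("candidates must be sorted and non-overlapping")
    events: list[BowelSoundEvent] = []
    group: list[tuple[float, float]] = []
    for cand in cands:
        if group and cand[0] - group[-1][1] > merge_gap_s + 1e-12:
            events.append(_finish_group(group))
            group = []
        group.append(cand)
    if group:
        events.append(_finish_group(group))
    return events


def _finish_group(group: list[tuple[float, float]]) -> BowelSoundEvent:
    return BowelSoundEvent(start_s=group[0][0], end_s=group[-1][1],
                           burst_spans=list(group))


def detect(model: BSDetector, rec: AudioRecording,
           hop_s: float = DEFAULT_HOP_S,
           min_run: int = DEFAULT_MIN_RUN,
           merge_gap_s: float = DEFAULT_MERGE_GAP_S,
           apply_highpass: bool = True) -> list[BowelSoundEvent]:
    """Full pipeline: high-pass -> sweep -> run-length rule -> merge."""
    track = sweep(model, rec, hop_s=hop_s, apply_highpass=apply_highpass)
    candidates = runs_to_candidates(track, min_run=min_run)
    events = merge_events(candidates, merge_gap_s=merge_gap_s)
    for ev in events:
        ev.n_windows = int(round(sum(e - s for s, e in ev.burst_spans) / hop_s))
    return events


def events_to_labels(events: Sequence[BowelSoundEvent]) -> list[LabelInterval]:
    return [LabelInterval(ev.start_s, ev.end_s, ev.label) for ev in events]


def match_events(detected: Sequence[BowelSoundEvent],
                 truth: Sequence[LabelInterval],
                 tol_s: float = 0.100) -> list[tuple[int, int]]:
    """Greedy 1:1 matching of detected events to truth intervals.

    A pair matches when both boundaries agree within ``tol_s`` or the
    intervals overlap; pairs are taken in order of decreasing overlap.
    """
    pairs = []
    for i, ev in enumerate(detected):
        for j, iv in enumerate(truth):
            ov = min(ev.end_s, iv.end_s) - max(ev.start_s, iv.start_s)
            near = (abs(ev.start_s - iv.start_s) <= tol_s
                    and abs(ev.end_s - iv.end_s) <= tol_s)
            if ov > 0 or near:
                pairs.append((ov, i, j))
    pairs.sort(reverse=True)
    used_i, used_j, out = set(), set(), []
    for _, i, j in pairs:
        if i not in used_i and j not in used_j:
            out.append((i, j))
            used_i.add(i)
            used_j.add(j)
    return sorted(out)
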