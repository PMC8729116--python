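"""Fasted vs fed comparison of the acoustic features.

Per channel (RLQ, LUQ) and per feature (duration/min, SC, SBW, MCR) the
fasted and fed values — one per subject, the per-recording aggregates
from :mod:`borborygmi.acoustics` — are compared with a two-sided paired
Wilcoxon signed-rank test.  Exactly 4 features x 2 channels = 8
comparisons are made, and p-values are Bonferroni-adjusted with m = 8.
Significance is annotated at adjusted p < 0.05 and < 0.01.

The signed-rank-over-subjects pairing is the default; pooling all events
and using a rank-sum test instead is available via ``paired=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .acoustics import RecordingFeatures

FEATURES = ("duration_per_min", "sc_hz", "sbw_hz", "mcr")
FEATURE_NAMES = {"duration_per_min": "Duration", "sc_hz": "SC",
                 "sbw_hz": "SBW", "mcr": "MCR"}
N_COMPARISONS = 8  # 4 features x 2 channels


@dataclass
class ComparisonResult:
    """One fasted-vs-fed comparison (one feature on one channel)."""

    feature: str
    channel: str
    n_pairs: int
    median_fasted: float
    iqr_fasted: float
    median_fed: float
    iqr_fed: float
    p_raw: float
    p_adj: float
    degenerate: bool = False

    @property
    def significant_05(self) -> bool:
        return self.p_adj < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_adj < 0.01

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant_05"] = self.significant_05
        d["significant_01"] = self.significant_01
        return d


def wilcoxon_paired(before: Sequence[float], after: Sequence[float],
                    exact_max_n: int = 25) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon convention).  The exact null
    distribution is used for n <= ``exact_max_n`` (falling back to the
    normal approximation when ties make the exact computation unsound);
    larger n uses the normal approximation with continuity correction.

    Returns ``(p, degenerate)`` where degenerate means all differences
    were zero (p reported as 1).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before and after must have equal length")
    keep = ~(np.isnan(b) | np.isnan(a))
    b, a = b[keep], a[keep]
    if b.size < 5:
        raise ValueError(f"need >= 5 complete pairs, got {b.size}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, True
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return float(res.pvalue), False


def bonferroni(p_raw: float, m: int = N_COMPARISONS) -> float:
    return min(1.0, m * p_raw)


def features_to_frame(feats: Iterable[RecordingFeatures]) -> pd.DataFrame:
    rows = []
    for f in feats:
        rows.append({
            "subject": f.subject_id, "channel": str(f.channel.value),
            "state": f.state, "duration_per_min": f.duration_per_min,
            "sc_hz": f.sc_hz, "sbw_hz": f.sbw_hz, "mcr": f.mcr,
            "n_events": f.n_events,
        })
    return pd.DataFrame(rows)


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    return float(q3 - q1)


def compare_cohort(features: pd.DataFrame | Iterable[RecordingFeatures],
                   paired: bool = True,
                   m: int = N_COMPARISONS) -> list[ComparisonResult]:
    """The 8 fasted-vs-fed comparisons with Bonferroni correction.

    ``features`` needs columns subject / channel / state plus the four
    feature columns; exactly the states ``fasted`` and ``fed`` are
    compared.  Subjects missing a state (or a feature value) are dropped
    pairwise.  ``paired=False`` pools values and uses the rank-sum test.
    """
    if not isinstance(features, pd.DataFrame):
        features = features_to_frame(features)
    channels = sorted(features["channel"].unique())
    if len(channels) != 2:
        raise ValueError(f"expected exactly 2 channels, got {channels}")
    results: list[ComparisonResult] = []
    for channel in channels:
        sub = features[features["channel"] == channel]
        for feat in FEATURES:
            piv = sub.pivot_table(index="subject", columns="state",
                                  values=feat, aggfunc="first")
            if not {"fasted", "fed"}.issubset(piv.columns):
                raise ValueError(f"both states required on channel {channel}")
            piv = piv.dropna(subset=["fasted", "fed"])
            fasted = piv["fasted"].to_numpy(dtype=float)
            fed = piv["fed"].to_numpy(dtype=float)
            if paired:
                p_raw, degen = wilcoxon_paired(fasted, fed)
            else:
                degen = False
                p_raw = float(sps.mannwhitneyu(fasted, fed,
                                               alternative="two-sided").pvalue)
            results.append(ComparisonResult(
                feature=FEATURE_NAMES[feat], channel=channel,
                n_pairs=int(fasted.size),
                median_fasted=float(np.median(fasted)), iqr_fasted=_iqr(fasted),
                median_fed=float(np.median(fed)), iqr_fed=_iqr(fed),
                p_raw=p_raw, p_adj=bonferroni(p_raw, m), degenerate=degen,
            ))
    assert len(results) == len(channels) * len(FEATURES)
    return results


def summary_table(features: pd.DataFrame | Iterable[RecordingFeatures]) -> pd.DataFrame:
    """Median (IQR) grid: rows = features, columns = channel x state."""
    if not isinstance(features, pd.DataFrame):
        features = features_to_frame(features)
    if features.empty:
        raise ValueError("empty feature table")
    cols = []
    data: dict[tuple[str, str], list[str]] = {}
    for channel in sorted(features["channel"].unique()):
        for state in ("fasted", "fed"):
            sel = features[(features["channel"] == channel)
                           & (features["state"] == state)]
            col = []
            for feat in FEATURES:
                v = sel[feat].dropna().to_numpy(dtype=float)
                if v.size == 0:
                    col.append("-")
                else:
                    med, iqr = np.median(v), _iqr(v)
                    digits = 3 if np.abs(med) < 1 else 1
                    col.append(f"{med:.{digits}f} ({iqr:.{digits}f})")
            data[(channel, state)] = col
            cols.append((channel, state))
    return pd.DataFrame(data, index=[FEATURE_NAMES[f] for f in FEATURES],
                        columns=pd.MultiIndex.from_tuples(cols,
                                                          names=["channel", "state"]))


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
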