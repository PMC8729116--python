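"""Standard evaluation protocol on simulated data.

This module pins down the reference conditions under which the pipeline
is validated, so that tests, scripts and documentation all exercise the
same study design:

* a balanced classifier corpus of >= 8,000 Mel samples sliced from
  simulated recordings (subtype-coverage-balanced mix, 22 minutes of
  audio), split 70/30 into training and validation;
* the default detector (three conv stages, Adadelta, 30 epochs, batch
  128) trained on that corpus;
* a label-shuffled control training (same data, permuted labels) whose
  validation accuracy must hover at chance;
* a held-out subtype corpus providing several hundred tagged samples per
  BS subtype for per-subtype detection accuracy;
* paired fasted/fed cohorts of 20 subjects, two channels, 90 s per
  state, with the fed state at 1.6x the event rate and 0.85x the
  spectral bandwidth (mean-crossing ratio untouched), plus a null
  configuration with identical states for false-positive calibration.

Recording lengths are scaled down from hours to tens of seconds; event
rates are per-minute, so the paired statistics see the same structure at
a fraction of the audio volume.
"""

from __future__ import annotations

import numpy as np

from .detector import BSDetector, DetectorConfig, EvalMetrics, train_val_split
from .features import MelDataset, PreprocessConfig, slice_dataset
from .simulate import (
    ConditionConfig,
    detector_training_condition,
    fasted_condition,
    fed_condition,
    generate_cohort,
    training_corpus,
)
from .acoustics import cohort_features
from .stats import compare_cohort, features_to_frame

#: audio volume used to build the balanced classifier corpus (seconds)
CORPUS_DURATION_S = 1320.0
#: audio volume for the held-out per-subtype evaluation corpus (seconds)
HOLDOUT_DURATION_S = 800.0
#: subtype mix of the held-out corpus: SB-heavy so that single bursts
#: (one slice each) still reach a few hundred samples
HOLDOUT_MIX = {"SB": 0.45, "MB": 0.25, "CRS": 0.15, "HS": 0.15}
#: paired-cohort design
N_SUBJECTS = 20
PER_STATE_DURATION_S = 90.0
#: fed-state effect sizes recovered by the statistics
FED_DURATION_FACTOR = 1.6
FED_SBW_SCALE = 0.85


def build_classifier_corpus(seed: int = 0,
                            duration_s: float = CORPUS_DURATION_S) -> MelDataset:
    """Balanced labelled Mel-sample dataset from simulated recordings."""
    corpus = training_corpus(duration_s, detector_training_condition(),
                             seed=seed)
    return slice_dataset(corpus, PreprocessConfig(), seed=seed, balance=True)


def build_subtype_holdout(seed: int = 1,
                          duration_s: float = HOLDOUT_DURATION_S) -> MelDataset:
    """Held-out corpus with subtype-tagged positives (natural negatives)."""
    cond = ConditionConfig(subtype_mix=HOLDOUT_MIX)
    corpus = training_corpus(duration_s, cond, seed=seed)
    return slice_dataset(corpus, PreprocessConfig(), seed=seed, balance=False)


def train_default_detector(ds: MelDataset, seed: int = 0, epochs: int = 30,
                           val_frac: float = 0.3,
                           verbose: bool = False) -> tuple[BSDetector, EvalMetrics]:
    """Train the default architecture; returns the model and val metrics."""
    tr, va = train_val_split(ds, val_frac, seed)
    det = BSDetector(DetectorConfig(epochs=epochs, seed=seed))
    det.train(tr, va, verbose=verbose)
    return det, det.evaluate(va)


def shuffled_label_control(ds: MelDataset, seed: int = 0,
                           epochs: int = 5, val_frac: float = 0.3) -> float:
    """Validation accuracy after training on label-shuffled data.

    The validation labels are left intact; with all signal destroyed in
    training, accuracy must stay at chance.  A few epochs suffice for
    the network to settle at its label-free behaviour.
    """
    rng = np.random.default_rng(seed)
    tr, va = train_val_split(ds, val_frac, seed)
    shuffled = MelDataset(tr.X, rng.permutation(tr.y), tr.subtype,
                          tr.origin_s, tr.config)
    det = BSDetector(DetectorConfig(epochs=epochs, seed=seed))
    det.train(shuffled, va)
    return float(det.history["val_accuracy"][-1])


def food_effect_replicate(seed: int, effect: bool = True,
                          n_subjects: int = N_SUBJECTS,
                          per_state_duration_s: float = PER_STATE_DURATION_S) -> dict:
    """One paired-cohort comparison; returns per-feature significance.

    ``effect=False`` runs the null configuration (fed identical to
    fasted), used to calibrate the family-wise false-positive rate.
    Features are computed from the simulator's ground-truth intervals so
    the statistics are isolated from detector error.
    """
    fasted = fasted_condition()
    if effect:
        fed = fed_condition(fasted, duration_factor=FED_DURATION_FACTOR,
                            sbw_scale=FED_SBW_SCALE)
    else:
        fed = fasted.replace(state="fed")
    cohort = generate_cohort(n_subjects, fasted, fed,
                             per_state_duration_s, seed=seed)
    results = compare_cohort(features_to_frame(cohort_features(cohort)))
    sig = {(r.channel, r.feature): r.significant_05 for r in results}
    return {
        "duration_significant": all(sig[(c, "Duration")] for c in ("RLQ", "LUQ")),
        "sbw_significant": all(sig[(c, "SBW")] for c in ("RLQ", "LUQ")),
        "mcr_significant": any(sig[(c, "MCR")] for c in ("RLQ", "LUQ")),
        "any_significant": any(sig.values()),
        "results": results,
    }
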