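"""Synthetic bowel-sound generator: morphology, arrivals, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from borborygmi.audio_io import Channel
from borborygmi.simulate import (
    ConditionConfig,
    DURATION_BOUNDS_S,
    HS_MAX_FREQ_HZ,
    MIN_EVENT_GAP_S,
    SubtypeParams,
    default_subtype_params,
    fasted_condition,
    fed_condition,
    generate_cohort,
    generate_recording,
    synth_event,
)

FS = 11025


class TestSynthEvent:
    @pytest.mark.parametrize("seed", range(5))
    def test_sb_duration_in_20_40_ms(self, seed):
        params = default_subtype_params()["SB"]
        _, dur = synth_event(params, FS, seed)
        assert 0.02 <= dur <= 0.04

    @pytest.mark.parametrize("seed", range(5))
    def test_hs_power_below_4khz(self, seed):
        params = default_subtype_params()["HS"]
        params.n_harmonics_range = (12, 12)
        wave, _ = synth_event(params, FS, seed)
        spec = np.abs(np.fft.rfft(wave)) ** 2
        freqs = np.fft.rfftfreq(wave.size, 1 / FS)
        assert spec[freqs <= HS_MAX_FREQ_HZ].sum() >= 0.99 * spec.sum()

    @pytest.mark.parametrize("seed", range(5))
    def test_mb_has_expected_burst_clusters(self, seed):
        params = default_subtype_params()["MB"]
        params.burst_count_range = (3, 3)
        params.intra_gap_range_s = (0.050, 0.050)
        wave, _ = synth_event(params, FS, seed)
        # envelope-threshold oracle: rises of the 10 ms-smoothed envelope
        # above 10% of its peak mark the burst clusters
        env = np.abs(wave)
        k = int(0.010 * FS)
        smooth = np.convolve(env, np.ones(k) / k, mode="same")
        active = smooth > 0.1 * smooth.max()
        n_clusters = int(np.sum(np.diff(active.astype(int)) == 1)
                         + (1 if active[0] else 0))
        assert n_clusters == 3

    @pytest.mark.parametrize("kind", ["SB", "MB", "CRS", "HS"])
    def test_durations_within_global_bounds(self, kind):
        params = default_subtype_params()[kind]
        for seed in range(8):
            wave, dur = synth_event(params, FS, seed)
            assert DURATION_BOUNDS_S[0] <= dur <= DURATION_BOUNDS_S[1] + 1e-9
            assert np.all(np.isfinite(wave))

    def test_amplitude_within_range(self):
        params = default_subtype_params()["CRS"]
        for seed in range(5):
            wave, _ = synth_event(params, FS, seed)
            lo, hi = params.amplitude_range
            assert lo - 1e-6 <= np.max(np.abs(wave)) <= hi + 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SubtypeParams("SB", (0.5, 0.1), (300, 500))
        with pytest.raises(ValueError):
            SubtypeParams("SB", (0.01, 0.04), (300, 500))  # below 20 ms floor
        with pytest.raises(ValueError):
            SubtypeParams("XX", (0.02, 0.04), (300, 500))


class TestGenerateRecording:
    def test_zero_rate_gives_pure_noise(self):
        sim = generate_recording(10.0, ConditionConfig(events_per_minute=0.0),
                                 FS, seed=3)
        assert sim.truth == []
        assert np.all(np.abs(sim.audio.samples) < 0.05)

    def test_determinism(self):
        a = generate_recording(20.0, fasted_condition(), FS, seed=42)
        b = generate_recording(20.0, fasted_condition(), FS, seed=42)
        assert np.array_equal(a.audio.samples, b.audio.samples)
        assert a.truth == b.truth

    def test_event_count_within_poisson_interval(self):
        cond = ConditionConfig(events_per_minute=20.0)
        sim = generate_recording(120.0, cond, FS, seed=0)
        lo, hi = sps.poisson.ppf([0.005, 0.995], 40.0)
        assert lo <= len(sim.truth) <= hi

    def test_events_keep_guard_gap(self):
        sim = generate_recording(60.0, fasted_condition(), FS, seed=1)
        ivs = sorted(sim.truth, key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start_s - a.end_s >= MIN_EVENT_GAP_S - 1e-9

    def test_truth_within_recording(self):
        sim = generate_recording(30.0, fasted_condition(), FS, seed=2)
        for iv in sim.truth:
            assert 0.0 <= iv.start_s < iv.end_s <= sim.audio.duration_s + 1e-9
            assert iv.label in {"SB", "MB", "CRS", "HS"}

    def test_infeasible_density_raises(self):
        cond = ConditionConfig(events_per_minute=2000.0)
        with pytest.raises(RuntimeError, match="achieved"):
            generate_recording(20.0, cond, FS, seed=0)

    def test_subtype_mix_chi_square(self):
        # pool events from several recordings; GoF vs configured mix
        cond = fasted_condition()
        counts = {k: 0 for k in cond.subtype_mix}
        total = 0
        seed = 0
        while total < 2000:
            sim = generate_recording(120.0, cond, FS, seed=seed)
            for iv in sim.truth:
                counts[iv.label] += 1
                total += 1
            seed += 1
        kinds = list(cond.subtype_mix)
        obs = np.array([counts[k] for k in kinds], dtype=float)
        exp = np.array([cond.subtype_mix[k] for k in kinds]) * obs.sum()
        p = sps.chisquare(obs, exp).pvalue
        assert p > 0.01


class TestGenerateCohort:
    def test_recording_count_and_pairing(self):
        fasted = fasted_condition()
        cohort = generate_cohort(5, fasted, fed_condition(fasted),
                                 per_state_duration_s=5.0, seed=0)
        assert len(cohort) == 20  # 5 subjects x 2 channels x 2 states
        keys = {(r.subject_id, r.channel, r.state) for r in cohort}
        assert len(keys) == 20
        assert {r.channel for r in cohort} == {Channel.RLQ, Channel.LUQ}
        assert {r.state for r in cohort} == {"fasted", "fed"}

    def test_fed_rate_raises_truth_duration(self):
        fasted = fasted_condition()
        cohort = generate_cohort(6, fasted, fed_condition(fasted),
                                 per_state_duration_s=40.0, seed=3)
        def mean_dur(state):
            recs = [r for r in cohort if r.state == state]
            return np.mean([sum(iv.duration_s for iv in r.sim.truth)
                            / r.sim.audio.duration_s for r in recs])
        assert mean_dur("fed") > mean_dur("fasted")

    def test_determinism(self):
        fasted = fasted_condition()
        a = generate_cohort(2, fasted, fed_condition(fasted), 5.0, seed=9)
        b = generate_cohort(2, fasted, fed_condition(fasted), 5.0, seed=9)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.sim.audio.samples, rb.sim.audio.samples)

    def test_requires_subjects(self):
        with pytest.raises(ValueError):
            generate_cohort(0, fasted_condition(), fed_condition(), 5.0)


class TestConditionConfig:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ConditionConfig(subtype_mix={"SB": 0.5, "MB": 0.4})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ConditionConfig(events_per_minute=-1.0)

    def test_fed_condition_scales(self):
        fasted = fasted_condition()
        fed = fed_condition(fasted, duration_factor=1.6, sbw_scale=0.85)
        assert fed.events_per_minute == pytest.approx(1.6 * fasted.events_per_minute)
        assert fed.sbw_scale == pytest.approx(0.85)
        assert fed.state == "fed"
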