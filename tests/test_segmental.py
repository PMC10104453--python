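"""Voicing mask, phrase segmentation and utterance-level summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhf_voice import VoiceSpec, synth_mpt_trial, synth_voice
from adhf_voice.framewise import FrameTrack, TrackKind, creak_probability, track_f0
from adhf_voice.segmental import (
    PhraseSet,
    VoicedMask,
    build_voiced_mask,
    cpp_summary,
    creak_percent,
    f0_summary,
    max_phonation_time,
    percentile_filter,
    phrase_stats,
    segment_phrases,
)
from adhf_voice.signal_io import Task

STEP = 0.01


def track(values, kind=TrackKind.CREAK, step=STEP):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values)) * step + step / 2
    return FrameTrack(times, values, step, kind)


def mask_from_bools(voiced):
    """Voicing mask with every voiced frame attributed to positive F0."""
    voiced = np.asarray(voiced, dtype=bool)
    times = np.arange(len(voiced)) * STEP + STEP / 2
    return VoicedMask(
        times=times,
        step=STEP,
        f0_positive=voiced,
        creak_high=np.zeros(len(voiced), dtype=bool),
        in_phrase=np.zeros(len(voiced), dtype=bool),
    )


def brute_force_phrases(voiced, step=STEP, max_gap=0.5):
    """Independent oracle: merge voiced runs whose gap is <= max_gap."""
    intervals = []
    i = 0
    while i < len(voiced):
        if voiced[i]:
            j = i
            while j + 1 < len(voiced) and voiced[j + 1]:
                j += 1
            intervals.append([i * step, (j + 1) * step])
            i = j + 1
        else:
            i += 1
    merged = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= max_gap + 1e-9:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    return [tuple(m) for m in merged]


class TestBuildVoicedMask:
    def test_positive_f0_everywhere_is_all_voiced(self):
        f0 = track([120.0] * 50, TrackKind.F0)
        creak = track([0.0] * 50)
        assert build_voiced_mask(f0, creak).voiced.all()

    def test_high_creak_alone_is_voiced(self):
        f0 = track([0.0] * 50, TrackKind.F0)
        creak = track([0.9] * 50)
        mask = build_voiced_mask(f0, creak)
        assert mask.voiced.all()
        assert mask.creak_high.all() and not mask.f0_positive.any()

    def test_short_gap_filled_as_in_phrase(self):
        # voiced 0-1.0 s and 1.3-2.0 s; the 0.3 s gap joins the phrase
        f0_vals = [100.0] * 100 + [0.0] * 30 + [100.0] * 70
        mask = build_voiced_mask(track(f0_vals, TrackKind.F0), track([0.0] * 200))
        gap = slice(100, 130)
        assert mask.voiced[gap].all()
        assert mask.in_phrase[gap].all()
        assert not mask.f0_positive[gap].any()

    def test_long_gap_stays_unvoiced(self):
        f0_vals = [100.0] * 100 + [0.0] * 60 + [100.0] * 40
        mask = build_voiced_mask(track(f0_vals, TrackKind.F0), track([0.0] * 200))
        assert not mask.voiced[100:160].any()

    def test_empty_tracks_give_empty_mask(self):
        empty = FrameTrack(np.empty(0), np.empty(0), STEP, TrackKind.CREAK)
        assert len(build_voiced_mask(empty, empty)) == 0


class TestSegmentPhrases:
    def test_sub_half_second_gap_merges(self):
        voiced = [True] * 100 + [False] * 20 + [True] * 80
        phrases = segment_phrases(mask_from_bools(voiced))
        assert len(phrases) == 1
        assert phrases.phrases[0] == pytest.approx((0.0, 2.0))
        assert phrases.durations().sum() == pytest.approx(2.0)

    def test_long_gap_splits(self):
        voiced = [True] * 100 + [False] * 60 + [True] * 100
        phrases = segment_phrases(mask_from_bools(voiced))
        stats = phrase_stats(phrases)
        assert stats["phrase_count"] == 2
        assert stats["phrase_mean_dur"] == pytest.approx(1.0)
        assert stats["phrase_sd_dur"] == pytest.approx(0.0)

    def test_hand_traced_three_runs(self):
        # runs [0,0.4], [0.9,1.2], [2.0,2.5]: first gap 0.5 merges, second 0.8 splits
        voiced = (
            [True] * 40 + [False] * 50 + [True] * 30 + [False] * 80 + [True] * 50
        )
        phrases = segment_phrases(mask_from_bools(voiced))
        assert [tuple(np.round(p, 6)) for p in phrases.phrases] == [
            (0.0, 1.2),
            (2.0, 2.5),
        ]
        stats = phrase_stats(phrases)
        assert stats["phrase_median_dur"] == pytest.approx(0.85)

    def test_exactly_half_second_gap_merges(self):
        voiced = [True] * 10 + [False] * 50 + [True] * 10
        assert len(segment_phrases(mask_from_bools(voiced))) == 1

    def test_no_voiced_frames_gives_empty_set(self):
        phrases = segment_phrases(mask_from_bools([False] * 50))
        assert len(phrases) == 0
        assert all(math.isnan(v) for v in phrase_stats(phrases).values())

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=400))
    def test_matches_brute_force_oracle(self, voiced):
        got = segment_phrases(mask_from_bools(voiced)).phrases
        expected = brute_force_phrases(voiced)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=1e-9)


class TestPhraseStats:
    def test_fifty_percent_phrase_time(self):
        p = PhraseSet(phrases=((0.0, 1.0), (2.0, 3.0)), utterance_duration=4.0)
        stats = phrase_stats(p)
        assert stats["phrase_total_dur"] == pytest.approx(2.0)
        assert stats["phrase_pct"] == pytest.approx(50.0)

    def test_mixed_durations(self):
        p = PhraseSet(phrases=((0.0, 1.2), (2.0, 2.5)), utterance_duration=3.0)
        stats = phrase_stats(p)
        assert stats["phrase_mean_dur"] == pytest.approx(0.85)
        assert stats["phrase_total_dur"] == pytest.approx(1.7)
        assert stats["phrase_pct"] == pytest.approx(56.7, abs=0.05)

    def test_phrase_percent_bounded(self):
        p = PhraseSet(phrases=((0.0, 3.0),), utterance_duration=3.0)
        assert phrase_stats(p)["phrase_pct"] <= 100.0


class TestCreakPercent:
    def test_formula_arithmetic(self):
        creak = track([0.5] * 13 + [0.1] * 39)
        mask = mask_from_bools([True] * 52)
        assert creak_percent(creak, mask, 0.3) == pytest.approx(25.0)

    def test_extremes(self):
        mask = mask_from_bools([True] * 10)
        assert creak_percent(track([0.0] * 10), mask, 0.3) == 0.0
        assert creak_percent(track([0.9] * 10), mask, 0.3) == 100.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        creak = track(rng.random(200))
        mask = mask_from_bools(rng.random(200) < 0.7)
        if mask.voiced.any():
            assert creak_percent(creak, mask, 0.02) >= creak_percent(creak, mask, 0.3)

    def test_no_voiced_frames_is_missing(self):
        assert math.isnan(
            creak_percent(track([0.9] * 10), mask_from_bools([False] * 10), 0.3)
        )


class TestPercentileFilter:
    def test_constant_unchanged(self):
        np.testing.assert_array_equal(
            percentile_filter(np.full(9, 3.0)), np.full(9, 3.0)
        )

    def test_one_to_hundred(self):
        kept = percentile_filter(np.arange(1.0, 101.0), 5, 95)
        np.testing.assert_array_equal(kept, np.arange(6.0, 96.0))

    def test_single_element_unchanged(self):
        np.testing.assert_array_equal(percentile_filter(np.array([7.0])), [7.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_filter(np.array([]))


class TestF0Summary:
    def test_constant_track(self):
        s = f0_summary(track([120.0] * 60, TrackKind.F0), Task.SENTENCES)
        assert s["f0_mean"] == pytest.approx(120.0)
        assert s["f0_median"] == pytest.approx(120.0)
        assert s["f0_sd"] == pytest.approx(0.0)

    def test_vowel_sd_ignores_octave_errors(self):
        values = [100.0] * 96 + [200.0] * 4
        s = f0_summary(track(values, TrackKind.F0), Task.VOWEL)
        assert s["f0_sd"] == pytest.approx(0.0)

    def test_matches_brute_force_on_uniform_ramp(self):
        values = np.linspace(90.0, 110.0, 101)
        s = f0_summary(track(values, TrackKind.F0), Task.SENTENCES)
        kept = percentile_filter(values, 5, 95)
        assert s["f0_mean"] == pytest.approx(kept.mean())
        assert s["f0_sd"] == pytest.approx(kept.std(ddof=1))

    def test_all_unvoiced_missing(self):
        s = f0_summary(track([0.0] * 30, TrackKind.F0), Task.VOWEL)
        assert all(math.isnan(v) for v in s.values())


class TestCppSummary:
    def test_constant_on_voiced_frames(self):
        cpp = track([15.0] * 40, TrackKind.CPP)
        s = cpp_summary(cpp, mask_from_bools([True] * 40))
        assert s["cpp_mean"] == pytest.approx(15.0)
        assert s["cpp_sd"] == pytest.approx(0.0)

    def test_unvoiced_frames_ignored(self):
        cpp = track([15.0] * 20 + [99.0] * 20, TrackKind.CPP)
        mask = mask_from_bools([True] * 20 + [False] * 20)
        assert cpp_summary(cpp, mask)["cpp_mean"] == pytest.approx(15.0)

    def test_no_voiced_frames_missing(self):
        s = cpp_summary(track([15.0] * 10, TrackKind.CPP), mask_from_bools([False] * 10))
        assert math.isnan(s["cpp_mean"])


class TestMaxPhonationTime:
    def test_first_to_last_voiced_frame(self):
        voiced = np.zeros(1000, dtype=bool)
        voiced[50:981] = True  # frame centers 0.505 s .. 9.805 s
        assert max_phonation_time(mask_from_bools(voiced)) == pytest.approx(9.3)

    def test_single_voiced_frame_is_zero(self):
        voiced = np.zeros(100, dtype=bool)
        voiced[3] = True
        assert max_phonation_time(mask_from_bools(voiced)) == 0.0

    def test_no_voiced_frames_missing(self):
        assert math.isnan(max_phonation_time(mask_from_bools([False] * 10)))

    def test_end_to_end_phonation_recovery(self):
        wave = synth_mpt_trial(8.0, VoiceSpec(f0_contour=110.0, seed=6))
        f0 = track_f0(wave)
        creak = creak_probability(wave)
        mask = build_voiced_mask(f0, creak)
        assert max_phonation_time(mask) == pytest.approx(8.0, abs=0.05)


class TestScriptedPausePlan:
    def test_pause_plan_yields_three_phrases(self):
        # pauses {0.2, 0.7, 0.3, 0.9}: the 0.2 and 0.3 s gaps merge,
        # the 0.7 and 0.9 s pauses contain inhalations -> 3 phrases
        spec = VoiceSpec(
            f0_contour=120.0,
            pause_plan=(0.2, 0.7, 0.3, 0.9),
            duration=8.0,
            seed=9,
        )
        wave, truth = synth_voice(spec)
        assert len(truth.phrases) == 3
        f0 = track_f0(wave)
        creak = creak_probability(wave)
        phrases = segment_phrases(build_voiced_mask(f0, creak))
        assert len(phrases) == 3
        total = phrase_stats(phrases)["phrase_total_dur"]
        assert phrases.durations().sum() <= phrases.utterance_duration + 1e-9
        assert total == pytest.approx(8.0 - 0.7 - 0.9, abs=0.3)
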