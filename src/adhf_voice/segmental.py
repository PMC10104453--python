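"""Utterance-level features: voicing, speech phrases, summaries, MPT.

A frame is voiced if (1) the pitch tracker assigned it a non-zero F0,
(2) it lies within a speech phrase, or (3) its creak probability exceeds
0.8 (irregular phonation where the pitch tracker finds no F0).  A speech
phrase is the speech between two successive inhalations: voiced regions
separated by less than 500 ms belong to the same phrase, and pauses longer
than 500 ms are assumed to contain an inhalation.  Criterion (2) depends on
the phrases, which depend on voicing, so the mask is built in two passes:
first F0/creak voicing, then phrase construction, then in-phrase fill-in.

A gap of exactly 500 ms merges (the definition uses both "longer than
500 ms" for splitting and "less than 500 ms" for merging; the boundary is
assigned to merge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .framewise import (
    FrameTrack,
    cpp_track,
    creak_probability,
    perturbation_measures,
    track_f0,
)
from .signal_io import CONTINUOUS_TASKS, Task, Waveform

PHRASE_GAP_S = 0.5
CREAK_VOICING_THRESHOLD = 0.8
CREAK_PERCENT_THRESHOLDS = (0.02, 0.3)
PERCENTILE_RANGE = (5.0, 95.0)
VOWEL_F0_SD_BAND_HZ = 50.0
EDGE_SILENCE_KEEP_S = 1.0


@dataclass(frozen=True)
class VoicedMask:
    """Per-frame voicing on the 10 ms creak grid, with provenance flags."""

    times: np.ndarray            # frame centers (s)
    step: float                  # s
    f0_positive: np.ndarray      # bool
    creak_high: np.ndarray       # bool
    in_phrase: np.ndarray        # bool (added by the phrase fill-in pass)

    @property
    def voiced(self) -> np.ndarray:
        return self.f0_positive | self.creak_high | self.in_phrase

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PhraseSet:
    """Ordered, non-overlapping speech phrases within one utterance."""

    phrases: tuple[tuple[float, float], ...]
    utterance_duration: float

    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.phrases])

    def __len__(self) -> int:
        return len(self.phrases)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (first, last) frame indices."""
    out = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_frame_runs(
    runs: list[tuple[int, int]], times: np.ndarray, step: float, max_gap: float
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        gap = (times[a] - step / 2) - (times[merged[-1][1]] + step / 2)
        if gap <= max_gap + 1e-9:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def nearest_values(track: FrameTrack, grid_times: np.ndarray) -> np.ndarray:
    """Map a track's values onto a different frame grid by nearest time."""
    if len(track) == 0:
        return np.full(len(grid_times), np.nan)
    idx = np.searchsorted(track.times, grid_times)
    idx = np.clip(idx, 0, len(track) - 1)
    left = np.clip(idx - 1, 0, len(track) - 1)
    use_left = np.abs(grid_times - track.times[left]) <= np.abs(
        grid_times - track.times[idx]
    )
    idx[use_left] = left[use_left]
    return track.values[idx]


def build_voiced_mask(f0: FrameTrack, creak: FrameTrack) -> VoicedMask:
    """Two-pass voicing mask on the creak track's 10 ms grid."""
    times = creak.times
    if len(times) == 0:
        empty = np.zeros(0, dtype=bool)
        return VoicedMask(times, creak.step, empty, empty, empty)
    f0_on_grid = nearest_values(f0, times)
    f0_positive = np.nan_to_num(f0_on_grid) > 0
    creak_high = creak.values > CREAK_VOICING_THRESHOLD
    base = f0_positive | creak_high
    in_phrase = np.zeros(len(times), dtype=bool)
    merged = _merge_frame_runs(_runs(base), times, creak.step, PHRASE_GAP_S)
    for a, b in merged:
        in_phrase[a : b + 1] = True
    in_phrase &= ~base
    return VoicedMask(times, creak.step, f0_positive, creak_high, in_phrase)


def segment_phrases(
    mask: VoicedMask, utterance_duration: float | None = None
) -> PhraseSet:
    """Phrases = maximal voiced runs merged across gaps of <= 500 ms.

    Frame i spans [center - step/2, center + step/2]; a phrase runs from
    the start of its first frame to the end of its last.
    """
    dur = utterance_duration if utterance_duration is not None else (
        float(mask.times[-1] + mask.step / 2) if len(mask) else 0.0
    )
    merged = _merge_frame_runs(
        _runs(mask.voiced), mask.times, mask.step, PHRASE_GAP_S
    )
    phrases = tuple(
        (float(mask.times[a] - mask.step / 2), float(mask.times[b] + mask.step / 2))
        for a, b in merged
    )
    return PhraseSet(phrases=phrases, utterance_duration=dur)


def phrase_stats(p: PhraseSet) -> dict[str, float]:
    """Count, total/mean/median/SD phrase duration, and phrase percent.

    Phrase percent = total phrase duration / utterance duration × 100 — the
    share of time spent speaking rather than pausing.  SD is the sample SD,
    defined as 0 for a single phrase.  An empty set yields all-NaN.
    """
    if len(p) == 0 or p.utterance_duration <= 0:
        keys = ("phrase_count", "phrase_total_dur", "phrase_mean_dur",
                "phrase_median_dur", "phrase_sd_dur", "phrase_pct")
        return {k: math.nan for k in keys}
    d = p.durations()
    total = float(d.sum())
    return {
        "phrase_count": float(len(d)),
        "phrase_total_dur": total,
        "phrase_mean_dur": float(d.mean()),
        "phrase_median_dur": float(np.median(d)),
        "phrase_sd_dur": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "phrase_pct": 100.0 * total / p.utterance_duration,
    }


def creak_percent(creak: FrameTrack, mask: VoicedMask, threshold: float) -> float:
    """Percent of voiced frames whose creak probability exceeds `threshold`."""
    voiced = mask.voiced
    if not voiced.any():
        return math.nan
    return float(100.0 * np.mean(creak.values[voiced] > threshold))


def percentile_filter(
    values: np.ndarray, lo: float = PERCENTILE_RANGE[0], hi: float = PERCENTILE_RANGE[1]
) -> np.ndarray:
    """Retain values within the [lo, hi] empirical percentile band.

    Percentiles use linear interpolation; the bounds are inclusive.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_filter requires a nonempty input")
    p_lo, p_hi = np.percentile(values, [lo, hi])
    return values[(values >= p_lo) & (values <= p_hi)]


def _stats(values: np.ndarray) -> tuple[float, float, float]:
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), float(np.median(values)), sd


def f0_summary(f0: FrameTrack, task: Task) -> dict[str, float]:
    """Mean/median/SD of F0 over 5–95th-percentile-filtered voiced frames.

    For sustained vowels the SD is further restricted to frames within
    50 Hz of the median, so octave-type tracking errors (doubled or halved
    F0) do not inflate it.
    """
    voiced = f0.values[f0.values > 0]
    if voiced.size == 0:
        return {"f0_mean": math.nan, "f0_median": math.nan, "f0_sd": math.nan}
    kept = percentile_filter(voiced)
    mean, median, sd = _stats(kept)
    if task == Task.VOWEL:
        band = kept[np.abs(kept - np.median(kept)) <= VOWEL_F0_SD_BAND_HZ]
        sd = float(band.std(ddof=1)) if len(band) > 1 else 0.0
    return {"f0_mean": mean, "f0_median": median, "f0_sd": sd}


def cpp_summary(cpp: FrameTrack, mask: VoicedMask) -> dict[str, float]:
    """Mean/median/SD of voiced-frame CPP after 5–95 percentile filtering."""
    on_grid = nearest_values(cpp, mask.times) if len(mask) else np.empty(0)
    vals = on_grid[mask.voiced] if len(mask) else on_grid
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {"cpp_mean": math.nan, "cpp_median": math.nan, "cpp_sd": math.nan}
    kept = percentile_filter(vals)
    mean, median, sd = _stats(kept)
    return {"cpp_mean": mean, "cpp_median": median, "cpp_sd": sd}


def max_phonation_time(mask: VoicedMask) -> float:
    """Duration between the first and last voiced frames (NaN if none)."""
    idx = np.flatnonzero(mask.voiced)
    if idx.size == 0:
        return math.nan
    return float(mask.times[idx[-1]] - mask.times[idx[0]])


def trimmed_utterance_duration(mask: VoicedMask, recording_duration: float) -> float:
    """Recording length after trimming leading/trailing silence beyond 1 s.

    Keeps at most one second of dead air on either side of the speech, so
    phrase percent does not depend on how long the recorder idled.
    """
    idx = np.flatnonzero(mask.voiced)
    if idx.size == 0:
        return recording_duration
    start = max(0.0, float(mask.times[idx[0]]) - EDGE_SILENCE_KEEP_S)
    end = min(recording_duration, float(mask.times[idx[-1]]) + EDGE_SILENCE_KEEP_S)
    return end - start


def extract_task_features(w: Waveform, task: Task) -> dict[str, float]:
    """All applicable measures for one preprocessed task recording.

    Continuous-speech tasks get phrase measures; vowels get perturbation
    measures; the MPT task gets maximum phonation time; every task gets
    F0/CPP summaries and creak percents.  Missing measures are NaN.
    """
    f0 = track_f0(w)
    creak = creak_probability(w)
    cpp = cpp_track(w)
    mask = build_voiced_mask(f0, creak)

    measures: dict[str, float] = {}
    measures.update(f0_summary(f0, task))
    measures.update(cpp_summary(cpp, mask))
    for thr in CREAK_PERCENT_THRESHOLDS:
        key = f"creak_pct_{str(thr).replace('.', '')}"
        measures[key] = creak_percent(creak, mask, thr)

    if task in CONTINUOUS_TASKS:
        dur = trimmed_utterance_duration(mask, w.duration)
        phrases = segment_phrases(mask, utterance_duration=dur)
        measures.update(phrase_stats(phrases))
    if task == Task.VOWEL:
        pert = perturbation_measures(w)
        measures.update(
            jitter=pert.jitter_local,
            shimmer=pert.shimmer_local,
            hnr=pert.hnr,
            lh_ratio=pert.lh_ratio,
        )
    if task == Task.MPT:
        measures["mpt"] = max_phonation_time(mask)
    return measures
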