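"""Synthetic voice and cohort generation with exact ground truth.

The clinical recordings behind this analysis cannot be shared, so every
layer of the pipeline is exercised against synthetic stand-ins whose truth
is known by construction:

* ``synth_voice`` renders quasi-periodic voiced speech with a source-filter
  model — an exponentially decaying glottal pulse train (with per-cycle
  jitter and shimmer) driven through a fixed all-pole /a/-like resonator —
  plus controllable additive noise, creaky segments (low-F0 irregular
  pulses), and a scripted pause plan.  It returns the waveform together
  with frame-level F0/voicing/creak truth and the true phrase boundaries.

* ``synth_cohort`` generates a participant × day feature table in which
  each feature carries a *planted* paired admission→discharge effect size,
  via a latent severity that declines from admission (1) to discharge (0).
  Loadings are scaled so the population paired Cohen's d equals the target.

Acoustic realism is deliberately bounded at "one formant set": the features
under test (F0, CPP, creak, phrase timing, MPT) do not require natural
speech, and exact truth matters more than naturalness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter, resample_poly

from .signal_io import ANALYSIS_RATE, Sensor, Task, Waveform

#: Default planted paired effect sizes (admission→discharge), microphone
#: channel: negative = decreases at discharge.  Feature keys are
#: "<task>:<measure>".
DEFAULT_EFFECTS: dict[str, float] = {
    "rainbow:phrase_total_dur": -0.50,
    "passage2:phrase_total_dur": -0.50,
    "mpt:mpt": 0.49,
    "vowel:f0_mean": 0.35,
    "sentences:cpp_sd": -0.27,
    "sentences:cpp_mean": -0.25,
    "sentences:cpp_median": -0.22,
    "vowel:cpp_median": 0.21,
    "vowel:cpp_sd": -0.17,
    "vowel:cpp_mean": 0.17,
}

#: /a/-like formant frequencies and bandwidths (Hz) for the fixed resonator.
_FORMANTS = ((700.0, 130.0), (1220.0, 70.0), (2600.0, 160.0))

_TRUTH_STEP = 0.010  # s, frame grid of the emitted truth tracks


@dataclass(frozen=True)
class VoiceSpec:
    """Parameters of one synthetic utterance.

    f0_contour is either a constant (Hz) or a (start, end) pair interpreted
    as a linear glide across the voiced material.  ``creak_segments`` lists
    (start, end) intervals replaced by the creaky source: irregular pulses
    at 40–70 Hz with ≥10 % interval jitter and occasional secondary pulses.
    ``pause_plan`` lists silent gap durations inserted between equal-length
    voiced stretches.  ``snr`` is the additive-white-noise level in dB
    relative to the voiced signal (``inf`` = noiseless).

    ``jitter`` and ``shimmer`` are expressed on the *local* measure scale
    (mean absolute cycle-to-cycle change over the mean): the iid per-cycle
    perturbation SD is divided by 2/sqrt(pi) so that the expected local
    jitter/shimmer of the rendered signal equals the parameter.
    """

    f0_contour: float | tuple[float, float] = 120.0
    jitter: float = 0.0          # % cycle-length perturbation
    shimmer: float = 0.0         # % cycle-amplitude perturbation
    snr: float = math.inf        # dB
    creak_segments: tuple[tuple[float, float], ...] = ()
    pause_plan: tuple[float, ...] = ()
    duration: float = 3.0        # s
    seed: int = 0
    rate: int = ANALYSIS_RATE
    sensor: Sensor = Sensor.MIC

    def __post_init__(self) -> None:
        f = self.f0_contour
        lo, hi = (f, f) if np.isscalar(f) else (min(f), max(f))
        if lo < 40.0 or hi > 400.0:
            raise ValueError(f"f0_contour must stay within [40, 400] Hz, got {f}")
        if self.jitter < 0 or self.shimmer < 0:
            raise ValueError("jitter and shimmer must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if sum(self.pause_plan) >= self.duration:
            raise ValueError("pauses exceed total duration")


@dataclass(frozen=True)
class VoiceTruth:
    """Ground truth emitted alongside a synthetic waveform."""

    times: np.ndarray        # truth frame times (s), 10 ms grid
    f0: np.ndarray           # true F0 per frame (Hz), 0 = unvoiced
    voiced: np.ndarray       # bool per frame
    creak: np.ndarray        # bool per frame (creaky source active)
    phrases: tuple[tuple[float, float], ...]  # true phrase intervals (500 ms rule)
    voiced_intervals: tuple[tuple[float, float], ...]
    pulse_times: np.ndarray  # glottal pulse instants (s)


def _resonator(x: np.ndarray, rate: int) -> np.ndarray:
    """Cascade of three two-pole resonators approximating an /a/ vowel."""
    y = x
    for freq, bw in _FORMANTS:
        r = math.exp(-math.pi * bw / rate)
        theta = 2.0 * math.pi * freq / rate
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        y = lfilter([1.0 - r], a, y)
    return y


_PULSE_TAU = 0.0005    # s, exponential decay constant of the glottal pulse
_PULSE_LEN = 0.004     # s, rendered pulse support
#: The source is rendered at this oversampling factor and decimated, so a
#: pulse's sub-sample timing survives band-limiting instead of aliasing
#: into spurious cycle-amplitude (shimmer) modulation.
_OVERSAMPLE = 8
#: E|e_i - e_{i-1}| for iid standard normal e: local jitter/shimmer of an
#: iid-perturbed cycle sequence is this factor times the perturbation SD,
#: so the VoiceSpec parameters are divided by it to land on the local measure.
_LOCAL_PERTURBATION_FACTOR = 2.0 / math.sqrt(math.pi)


def _add_pulse(source: np.ndarray, rate: int, t_pulse: float, amp: float) -> None:
    """Add an exponentially decaying pulse starting at the exact (fractional)
    time t_pulse, sampled on the output grid."""
    n = len(source)
    i0 = int(math.ceil(t_pulse * rate))
    i1 = min(n, i0 + int(_PULSE_LEN * rate))
    if i0 >= n or i1 <= i0:
        return
    t = np.arange(i0, i1) / rate - t_pulse
    source[i0:i1] += amp * np.exp(-t / _PULSE_TAU)


def _contour_f0(spec: VoiceSpec, t: float) -> float:
    if np.isscalar(spec.f0_contour):
        return float(spec.f0_contour)
    f0, f1 = spec.f0_contour
    frac = min(max(t / spec.duration, 0.0), 1.0)
    return f0 + (f1 - f0) * frac


def _voiced_intervals(spec: VoiceSpec) -> list[tuple[float, float]]:
    n_stretch = len(spec.pause_plan) + 1
    voiced_total = spec.duration - sum(spec.pause_plan)
    stretch = voiced_total / n_stretch
    intervals, t = [], 0.0
    for i in range(n_stretch):
        intervals.append((t, t + stretch))
        t += stretch
        if i < len(spec.pause_plan):
            t += spec.pause_plan[i]
    return intervals


def merge_intervals(
    intervals: list[tuple[float, float]], max_gap: float = 0.5
) -> list[tuple[float, float]]:
    """Merge intervals whose gap is <= max_gap (the 500 ms inhalation rule)."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start - merged[-1][1] <= max_gap + 1e-12:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]


def _in_segment(t: float, segments) -> bool:
    return any(s <= t < e for s, e in segments)


def synth_voice(spec: VoiceSpec) -> tuple[Waveform, VoiceTruth]:
    """Render a synthetic utterance and its ground truth.

    Deterministic for a fixed seed; a different seed redraws the stochastic
    components (jitter, shimmer, noise, creak pulse timing) but leaves the
    truth structure (voiced stretches, phrases) unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    hi_rate = rate * _OVERSAMPLE
    n = int(round(spec.duration * rate))
    source = np.zeros(n * _OVERSAMPLE)
    voiced_iv = _voiced_intervals(spec)
    pulse_times: list[float] = []
    jitter_sd = spec.jitter / 100.0 / _LOCAL_PERTURBATION_FACTOR
    shimmer_sd = spec.shimmer / 100.0 / _LOCAL_PERTURBATION_FACTOR

    for start, end in voiced_iv:
        t = start
        while t < end:
            creaky = _in_segment(t, spec.creak_segments)
            if creaky:
                f0c = rng.uniform(40.0, 70.0)
                period = (1.0 / f0c) * (1.0 + 0.15 * rng.standard_normal())
                period = max(period, 1.0 / 90.0)
                amp = 1.0 + 0.2 * rng.standard_normal()
                _add_pulse(source, hi_rate, t, amp)
                pulse_times.append(t)
                # occasional secondary (double) pulse within the cycle
                if rng.random() < 0.25:
                    t2 = t + 0.45 * period
                    if t2 < end:
                        _add_pulse(source, hi_rate, t2, 0.5 * amp)
                        pulse_times.append(t2)
            else:
                f0 = _contour_f0(spec, t)
                period = (1.0 / f0) * (1.0 + jitter_sd * rng.standard_normal())
                period = max(period, 1.0 / 500.0)
                amp = max(1.0 + shimmer_sd * rng.standard_normal(), 0.05)
                _add_pulse(source, hi_rate, t, amp)
                pulse_times.append(t)
            t += period

    source = resample_poly(source, 1, _OVERSAMPLE)[:n]
    voice = _resonator(source, rate)

    # zero out pauses exactly so silence is digital silence at snr = inf
    mask = np.zeros(n, dtype=bool)
    for start, end in voiced_iv:
        i0, i1 = int(round(start * rate)), int(round(end * rate))
        # allow the resonator ringing a short decay tail (5 ms)
        mask[i0 : min(n, i1 + int(0.005 * rate))] = True
    voice[~mask] = 0.0

    if math.isfinite(spec.snr):
        p_sig = float(np.mean(voice[mask] ** 2)) if mask.any() else 0.0
        noise = rng.standard_normal(n) * math.sqrt(p_sig * 10.0 ** (-spec.snr / 10.0))
        voice = voice + noise

    times = np.arange(0.0, spec.duration, _TRUTH_STEP)
    f0_truth = np.zeros_like(times)
    voiced_truth = np.zeros(len(times), dtype=bool)
    creak_truth = np.zeros(len(times), dtype=bool)
    for k, t in enumerate(times):
        if _in_segment(t, voiced_iv):
            voiced_truth[k] = True
            if _in_segment(t, spec.creak_segments):
                creak_truth[k] = True
            else:
                f0_truth[k] = _contour_f0(spec, t)

    truth = VoiceTruth(
        times=times,
        f0=f0_truth,
        voiced=voiced_truth,
        creak=creak_truth,
        phrases=tuple(merge_intervals(voiced_iv)),
        voiced_intervals=tuple(voiced_iv),
        pulse_times=np.asarray(pulse_times),
    )
    return Waveform(samples=voice, rate=rate, sensor=spec.sensor), truth


def synth_mpt_trial(
    duration: float, spec: VoiceSpec | None = None, pad: float = 0.3
) -> Waveform:
    """A single sustained phonation of given length with silent padding.

    duration = 0 yields a fully silent recording (MPT missing downstream).
    """
    base = spec or VoiceSpec()
    if duration <= 0:
        n = int(round(2 * pad * base.rate))
        return Waveform(samples=np.zeros(max(n, 1)), rate=base.rate, sensor=base.sensor)
    phon_spec = VoiceSpec(
        f0_contour=base.f0_contour,
        jitter=base.jitter,
        shimmer=base.shimmer,
        snr=base.snr,
        duration=duration,
        seed=base.seed,
        rate=base.rate,
        sensor=base.sensor,
    )
    wave, _ = synth_voice(phon_spec)
    pad_n = int(round(pad * base.rate))
    samples = np.concatenate([np.zeros(pad_n), wave.samples, np.zeros(pad_n)])
    return Waveform(samples=samples, rate=base.rate, sensor=base.sensor)


# ---------------------------------------------------------------------------
# Feature-level cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Statistical shape of a synthetic admission→discharge cohort.

    The defaults emulate the study cohort: 52 participants recorded over
    2–10 hospital days (a few with a single usable day), per-feature paired
    effect sizes matching the reported microphone-channel values, roughly
    half the cohort performing the maximum-phonation task, and a small
    per-cell missingness rate from failed or skipped recordings.
    """

    n_participants: int = 52
    day_range: tuple[int, int] = (2, 10)
    single_day_fraction: float = 3 / 52
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    between_sd: float = 1.0
    within_sd: float = 1.0
    missing_rate: float = 0.03
    mpt_available: float = 24 / 52
    severity_jitter: float = 0.12
    seed: int = 0
    sensor: Sensor = Sensor.MIC

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")
        for p in (self.single_day_fraction, self.missing_rate, self.mpt_available):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.within_sd <= 0 and any(d != 0 for d in self.effects.values()):
            raise ValueError(
                "within_sd must be positive to plant a finite paired effect: "
                "the paired d divides by the SD of day-to-day differences"
            )


@dataclass(frozen=True)
class CohortTruth:
    severity: pd.DataFrame          # participant, day, severity
    loadings: dict[str, float]      # per-feature severity loading
    effects: dict[str, float]       # planted paired d per feature


def synth_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a participant × day feature table with planted paired effects.

    Latent severity declines linearly from 1 (admission) to 0 (discharge)
    with per-day jitter; feature = participant offset + loading × severity
    + within-day noise.  The loading for target effect d* is
    ``-d* · sqrt(2) · within_sd`` so that the population paired Cohen's d of
    the admission→discharge change equals d* exactly.
    """
    rng = np.random.default_rng(spec.seed)
    features = list(spec.effects)
    loadings = {
        f: -d * math.sqrt(2.0) * spec.within_sd for f, d in spec.effects.items()
    }
    mpt_features = [f for f in features if f.startswith("mpt:")]
    has_mpt = rng.random(spec.n_participants) < spec.mpt_available

    rows, sev_rows = [], []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:03d}"
        if rng.random() < spec.single_day_fraction:
            days = [1]
        else:
            n_days = int(rng.integers(spec.day_range[0], spec.day_range[1] + 1))
            days = list(range(1, n_days + 1))
        baseline = {f: rng.normal(0.0, spec.between_sd) for f in features}
        for d in days:
            if len(days) == 1:
                sev = 1.0
            else:
                frac = (d - 1) / (len(days) - 1)
                sev = 1.0 - frac
                if 0 < frac < 1:  # intermediate days jitter around the line
                    sev = float(np.clip(sev + rng.normal(0.0, spec.severity_jitter), 0.0, 1.0))
            sev_rows.append({"participant": pid, "day": d, "severity": sev})
            row: dict[str, object] = {
                "participant": pid,
                "day": d,
                "sensor": spec.sensor.value,
            }
            for f in features:
                if f in mpt_features and not has_mpt[i]:
                    row[f] = np.nan
                    continue
                value = baseline[f] + loadings[f] * sev + rng.normal(0.0, spec.within_sd)
                if rng.random() < spec.missing_rate:
                    value = np.nan
                row[f] = value
            rows.append(row)

    table = pd.DataFrame(rows)
    truth = CohortTruth(
        severity=pd.DataFrame(sev_rows),
        loadings=loadings,
        effects=dict(spec.effects),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Audio-level cohort mode (integration testing)


def synth_audio_session(
    severity: float, seed: int, rate: int = ANALYSIS_RATE, sensor: Sensor = Sensor.MIC
) -> dict[Task, Waveform]:
    """Render one day's recordings whose acoustics track a severity in [0, 1].

    Higher severity (admission) maps to noisier phonation (lower CPP),
    lower and less steady F0, slower reading with longer pauses, and a
    shorter maximum phonation.  Used by integration tests and examples to
    exercise the full audio → features → classifier path.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    f0 = 115.0 * (1.0 + 0.12 * (1.0 - severity)) + rng.normal(0.0, 2.0)
    snr = 28.0 - 16.0 * severity
    jitter = 0.5 + 1.5 * severity

    vowel_spec = VoiceSpec(
        f0_contour=f0, jitter=jitter, shimmer=2.0, snr=snr,
        duration=3.0, seed=int(rng.integers(2**31)), rate=rate, sensor=sensor,
    )
    vowel, _ = synth_voice(vowel_spec)

    # reading: 4 phrases; severity stretches phrases and pauses
    pauses = tuple(0.6 + 0.5 * severity + rng.uniform(0, 0.2) for _ in range(3))
    read_dur = 8.0 * (1.0 + 0.35 * severity) + sum(pauses)
    reading_spec = VoiceSpec(
        f0_contour=(f0, f0 * 0.92), jitter=jitter, shimmer=2.0, snr=snr,
        pause_plan=pauses, duration=read_dur,
        seed=int(rng.integers(2**31)), rate=rate, sensor=sensor,
    )
    reading, _ = synth_voice(reading_spec)

    mpt_dur = 10.0 - 4.5 * severity + rng.normal(0.0, 0.5)
    mpt = synth_mpt_trial(
        max(mpt_dur, 2.0),
        VoiceSpec(f0_contour=f0, jitter=jitter, snr=snr,
                  seed=int(rng.integers(2**31)), rate=rate, sensor=sensor),
    )
    return {Task.VOWEL: vowel, Task.RAINBOW: reading, Task.MPT: mpt}


def synth_audio_cohort(
    n_participants: int = 8, seed: int = 0, rate: int = ANALYSIS_RATE
) -> list[tuple[str, int, float, dict[Task, Waveform]]]:
    """Two-day (admission, discharge) audio cohort with known severities.

    Returns (participant, day, severity, task → waveform) tuples.
    """
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_participants):
        pid = f"A{i + 1:03d}"
        for day, sev in ((1, 1.0), (2, 0.0)):
            recs = synth_audio_session(sev, seed=int(rng.integers(2**31)), rate=rate)
            sessions.append((pid, day, sev, recs))
    return sessions
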