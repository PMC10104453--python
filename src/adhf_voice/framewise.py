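"""Frame-level acoustic analysis: F0, cepstral peak prominence, creak.

All trackers assume the 25 kHz analysis rate set by preprocessing.  Frame
steps are exact sample counts nearest the nominal 3.3 / 10 / 10.24 ms
(82 / 250 / 256 samples) so that repeated runs are bit-reproducible.

* F0 is tracked by windowed normalized cross-correlation (40 ms Hann
  window every 3.3 ms) with Viterbi path smoothing that penalizes octave
  jumps; unvoiced frames carry F0 = 0.
* CPP is the height in dB of the cepstral peak — restricted to quefrencies
  of 3.3–16.7 ms, i.e. F0 between 60 and 300 Hz — above a straight-line
  noise floor regressed over the same quefrency range (40.96 ms window
  every 10.24 ms).  Higher CPP indicates more periodic, healthier voice.
* Creak probability comes from a logistic combiner over four bounded
  descriptors of glottal-pulse irregularity (power-contour slope,
  intra-frame periodicity, inter-pulse similarity, subharmonic/widely
  spaced pulse evidence), computed every 10 ms.  The combiner was fitted
  once on labelled frames from the synthetic generator and its
  coefficients are shipped as package constants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, get_window, hilbert, welch

from .signal_io import ANALYSIS_RATE, Waveform

F0_STEP_SAMPLES = 82       # ~3.3 ms at 25 kHz
F0_WINDOW_S = 0.040
CPP_STEP_SAMPLES = 256     # ~10.24 ms
CPP_WINDOW_SAMPLES = 1024  # ~40.96 ms
CREAK_STEP_SAMPLES = 250   # 10 ms
CPP_QUEFRENCY_RANGE_S = (0.0033, 0.0167)   # F0 300 down to ~60 Hz
DEFAULT_F0_RANGE_HZ = (60.0, 300.0)
VOICING_THRESHOLD = 0.45
SILENCE_THRESHOLD_DB = 40.0   # frames this far below the utterance max are unvoiced
OCTAVE_JUMP_COST = 0.35       # per octave of F0 movement between frames
VOICED_UNVOICED_COST = 0.14
LH_RATIO_CUT_HZ = 4000.0


class TrackKind(str, enum.Enum):
    F0 = "f0"
    CPP = "cpp"
    CREAK = "creak"


@dataclass(frozen=True)
class FrameTrack:
    """Uniformly spaced per-frame values (times are frame centers)."""

    times: np.ndarray
    values: np.ndarray
    step: float
    kind: TrackKind

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PerturbationSet:
    """Cycle-level voice perturbation measures from a sustained vowel."""

    jitter_local: float   # %
    shimmer_local: float  # %
    hnr: float            # dB
    lh_ratio: float       # dB, low-band minus high-band energy

    def is_missing(self) -> bool:
        return math.isnan(self.jitter_local)


MISSING_PERTURBATION = PerturbationSet(math.nan, math.nan, math.nan, math.nan)


@dataclass(frozen=True)
class CreakFeatureVector:
    power_slope: float              # dB/frame, clipped to [-50, 50]
    intraframe_periodicity: float   # [0, 1]
    interpulse_similarity: float    # [0, 1]
    subharmonic_score: float        # [0, 1]

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.power_slope,
                self.intraframe_periodicity,
                self.interpulse_similarity,
                self.subharmonic_score,
            ]
        )


# ---------------------------------------------------------------------------
# F0 tracking


def _frame_candidates(r: np.ndarray, lag_min: int, n_best: int = 4):
    """Local maxima of the normalized cross-correlation, parabolic-refined."""
    cands = []
    for i in range(1, len(r) - 1):
        if r[i] >= r[i - 1] and r[i] > r[i + 1] and r[i] > 0.3:
            denom = r[i - 1] - 2 * r[i] + r[i + 1]
            delta = 0.5 * (r[i - 1] - r[i + 1]) / denom if denom < 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            strength = r[i] - 0.25 * (r[i - 1] - r[i + 1]) * delta
            cands.append((lag_min + i + delta, min(strength, 1.0)))
    cands.sort(key=lambda c: -c[1])
    return cands[:n_best]


def track_f0(
    w: Waveform,
    fmin: float = DEFAULT_F0_RANGE_HZ[0],
    fmax: float = DEFAULT_F0_RANGE_HZ[1],
    voicing_threshold: float = VOICING_THRESHOLD,
    silence_db: float = SILENCE_THRESHOLD_DB,
) -> FrameTrack:
    """Cross-correlation F0 track, 40 ms window every 3.3 ms.

    Each frame's value is the F0 of the lag maximizing the windowed
    normalized cross-correlation within [1/fmax, 1/fmin], or 0 when the
    frame fails the voicing criterion (correlation peak below
    `voicing_threshold`, or local RMS more than `silence_db` below the
    utterance maximum).  A Viterbi pass over per-frame candidates penalizes
    octave jumps.
    """
    rate = w.rate
    if not 0.0 < fmin < fmax < rate / 2:
        raise ValueError("require 0 < fmin < fmax < Nyquist")
    x = w.samples
    win = int(round(F0_WINDOW_S * rate))
    step = F0_STEP_SAMPLES if rate == ANALYSIS_RATE else max(1, int(round(0.0033 * rate)))
    lag_min = max(2, int(math.floor(rate / fmax)))
    lag_max = int(math.ceil(rate / fmin))
    ext_len = win + lag_max
    if len(x) < ext_len:
        return FrameTrack(np.empty(0), np.empty(0), step / rate, TrackKind.F0)

    starts = np.arange(0, len(x) - ext_len + 1, step)
    ext = np.lib.stride_tricks.sliding_window_view(x, ext_len)[starts]
    ext = ext - ext[:, :win].mean(axis=1, keepdims=True)
    a = ext[:, :win]

    nfft = 1 << int(math.ceil(math.log2(ext_len + win)))
    corr = np.fft.irfft(
        np.conj(np.fft.rfft(a, nfft)) * np.fft.rfft(ext, nfft), nfft
    )[:, : lag_max + 1]
    sq = np.concatenate([np.zeros((len(ext), 1)), np.cumsum(ext**2, axis=1)], axis=1)
    e0 = sq[:, win] - sq[:, 0]
    lags = np.arange(lag_max + 1)
    e_shift = sq[:, lags + win] - sq[:, lags]
    denom = np.sqrt(np.maximum(e0[:, None] * e_shift, 1e-300))
    r = corr / denom

    rms = np.sqrt(np.maximum(e0 / win, 0.0))
    rms_floor = rms.max() * 10.0 ** (-silence_db / 20.0) if rms.size else 0.0

    candidates = []
    for f in range(len(ext)):
        if rms[f] <= rms_floor or e0[f] <= 0:
            candidates.append([])
        else:
            candidates.append(_frame_candidates(r[f, lag_min:], lag_min))

    f0 = _viterbi_f0(candidates, rate, voicing_threshold)
    times = (starts + win / 2) / rate
    return FrameTrack(times, f0, step / rate, TrackKind.F0)


def _viterbi_f0(candidates, rate: float, voicing_threshold: float) -> np.ndarray:
    """Best F0 path; state 0 is 'unvoiced', others index frame candidates."""
    n = len(candidates)
    f0 = np.zeros(n)
    if n == 0:
        return f0
    # states: (freq or None, local score)
    prev_scores = None
    prev_states = None
    backptr = []
    for f in range(n):
        states = [(None, voicing_threshold)] + [
            (rate / lag, strength) for lag, strength in candidates[f]
        ]
        scores = np.empty(len(states))
        bp = np.zeros(len(states), dtype=int)
        if prev_scores is None:
            for s, (_, local) in enumerate(states):
                scores[s] = local
        else:
            for s, (freq, local) in enumerate(states):
                best, best_j = -np.inf, 0
                for j, (pfreq, _) in enumerate(prev_states):
                    if freq is None or pfreq is None:
                        cost = 0.0 if freq is None and pfreq is None else VOICED_UNVOICED_COST
                    else:
                        cost = OCTAVE_JUMP_COST * abs(math.log2(freq / pfreq))
                    val = prev_scores[j] - cost
                    if val > best:
                        best, best_j = val, j
                scores[s] = best + local
                bp[s] = best_j
        backptr.append(bp)
        prev_scores, prev_states = scores, states
        if f == n - 1:
            path = [int(np.argmax(scores))]
    for f in range(n - 1, 0, -1):
        path.append(int(backptr[f][path[-1]]))
    path.reverse()
    # decode frequencies by replaying states
    for f in range(n):
        s = path[f]
        if s > 0:
            lag, _ = candidates[f][s - 1]
            f0[f] = rate / lag
    return f0


# ---------------------------------------------------------------------------
# Cepstral peak prominence


def cepstral_peak(segment: np.ndarray, rate: int) -> tuple[float, float]:
    """CPP (dB) and peak quefrency (s) of one analysis frame.

    The power cepstrum of the Hann-windowed segment is searched between
    quefrencies of 3.3 and 16.7 ms; CPP is the peak level minus the value,
    at the peak quefrency, of the least-squares line fitted to the dB
    power cepstrum over that search range.
    """
    n = CPP_WINDOW_SAMPLES
    seg = np.asarray(segment, dtype=np.float64)
    if len(seg) != n:
        raise ValueError(f"expected {n}-sample frame, got {len(seg)}")
    if not np.any(seg):
        return math.nan, math.nan
    windowed = seg * get_window("hann", n, fftbins=True)
    spectrum = np.abs(np.fft.rfft(windowed, n)) ** 2
    log_spec = np.log(np.maximum(spectrum, 1e-280))
    ceps = np.fft.irfft(log_spec, n)[: n // 2 + 1]
    ceps_db = 10.0 * np.log10(np.maximum(ceps**2, 1e-280))
    k_lo = int(math.ceil(CPP_QUEFRENCY_RANGE_S[0] * rate))
    k_hi = int(math.floor(CPP_QUEFRENCY_RANGE_S[1] * rate))
    ks = np.arange(k_lo, k_hi + 1)
    band = ceps_db[k_lo : k_hi + 1]
    slope, intercept = np.polyfit(ks, band, 1)
    k_peak = ks[int(np.argmax(band))]
    cpp = float(ceps_db[k_peak] - (slope * k_peak + intercept))
    return cpp, k_peak / rate


def cpp_track(w: Waveform) -> FrameTrack:
    """CPP contour: 40.96 ms frames every 10.24 ms; all-zero frames are NaN."""
    x = w.samples
    n, step = CPP_WINDOW_SAMPLES, CPP_STEP_SAMPLES
    if len(x) < n:
        return FrameTrack(np.empty(0), np.empty(0), step / w.rate, TrackKind.CPP)
    starts = np.arange(0, len(x) - n + 1, step)
    values = np.empty(len(starts))
    for i, s in enumerate(starts):
        values[i], _ = cepstral_peak(x[s : s + n], w.rate)
    times = (starts + n / 2) / w.rate
    return FrameTrack(times, values, step / w.rate, TrackKind.CPP)


# ---------------------------------------------------------------------------
# Creak descriptors and probability

_CREAK_WINDOW_S = 0.100
_LONG_INTERVAL_S = 0.013   # modal F0 >= ~77 Hz gives shorter pulse intervals
_PULSE_SNIPPET_S = 0.004


def creak_features(w: Waveform, t: float) -> CreakFeatureVector:
    """Four bounded creak descriptors on a 100 ms window centered at t.

    A digitally silent window returns the all-zero vector.
    """
    rate = w.rate
    half = int(_CREAK_WINDOW_S * rate / 2)
    c = int(round(t * rate))
    seg = w.samples[max(0, c - half) : c + half]
    if len(seg) < half or not np.any(seg):
        return CreakFeatureVector(0.0, 0.0, 0.0, 0.0)

    # short-term power contour slope over 10 ms subframes
    sub = rate // 100
    n_sub = len(seg) // sub
    powers = (seg[: n_sub * sub].reshape(n_sub, sub) ** 2).mean(axis=1)
    power_db = 10.0 * np.log10(np.maximum(powers, 1e-280))
    slope = float(np.polyfit(np.arange(n_sub), power_db, 1)[0]) if n_sub >= 2 else 0.0
    slope = float(np.clip(slope, -50.0, 50.0))

    # intra-frame periodicity: peak normalized autocorrelation, 2-20 ms lags
    z = seg - seg.mean()
    lag_lo, lag_hi = int(0.002 * rate), min(int(0.020 * rate), len(z) - 2)
    periodicity = 0.0
    if lag_hi > lag_lo:
        nfft = 1 << int(math.ceil(math.log2(2 * len(z))))
        ac = np.fft.irfft(np.abs(np.fft.rfft(z, nfft)) ** 2, nfft)[: lag_hi + 1]
        if ac[0] > 0:
            lags = np.arange(lag_lo, lag_hi + 1)
            # unbias the rectangular-truncation taper (N-L)/N
            norm = ac[lag_lo : lag_hi + 1] / ac[0] * len(z) / (len(z) - lags)
            periodicity = float(np.clip(norm.max(), 0.0, 1.0))

    # glottal pulse instants from the amplitude envelope
    env = np.abs(hilbert(z))
    peaks, _ = find_peaks(
        env, height=0.3 * env.max(), distance=max(1, int(0.002 * rate))
    )
    similarity, subharmonic = 0.0, 0.0
    if len(peaks) >= 3:
        snip = int(_PULSE_SNIPPET_S * rate)
        sims = []
        for p0, p1 in zip(peaks[:-1], peaks[1:]):
            s0, s1 = seg[p0 : p0 + snip], seg[p1 : p1 + snip]
            m = min(len(s0), len(s1))
            if m < 8:
                continue
            s0, s1 = s0[:m] - s0[:m].mean(), s1[:m] - s1[:m].mean()
            d = np.linalg.norm(s0) * np.linalg.norm(s1)
            if d > 0:
                sims.append(float(np.dot(s0, s1) / d))
        if sims:
            similarity = float(np.clip(np.mean(sims), 0.0, 1.0))
        intervals = np.diff(peaks) / rate
        frac_long = float(np.mean(intervals > _LONG_INTERVAL_S))
        cv = float(intervals.std() / intervals.mean()) if intervals.mean() > 0 else 0.0
        subharmonic = float(np.clip(0.7 * frac_long + 0.3 * min(1.0, cv / 0.15), 0.0, 1.0))

    return CreakFeatureVector(slope, periodicity, similarity, subharmonic)


#: Logistic creak combiner fitted once on synthetic generator frames
#: (see `train_creak_detector`); z-scoring statistics and coefficients are
#: frozen here so detection is deterministic across installs.
CREAK_MODEL: dict[str, object] = {
    "feature_mean": np.array(
        [0.0044981082057644, 0.521803022916846, 0.2869686030794466, 0.45350662392291163]
    ),
    "feature_scale": np.array(
        [0.5208370535200784, 0.313549026463676, 0.40369830899497094, 0.22213718239184926]
    ),
    "coef": np.array([-0.0, -0.7689282833694814, 0.0, 6.477200462568587]),
    "intercept": 1.4668977894322053,
}


def creak_probability(w: Waveform, model: dict | None = None) -> FrameTrack:
    """Frame-by-frame creak probability every 10 ms, values in [0, 1]."""
    model = model or CREAK_MODEL
    step = CREAK_STEP_SAMPLES if w.rate == ANALYSIS_RATE else max(1, w.rate // 100)
    centers = np.arange(step // 2, len(w.samples), step)
    probs = np.empty(len(centers))
    mean = np.asarray(model["feature_mean"])
    scale = np.asarray(model["feature_scale"])
    coef = np.asarray(model["coef"])
    b0 = float(model["intercept"])
    for i, c in enumerate(centers):
        feats = creak_features(w, c / w.rate).as_array()
        z = (feats - mean) / scale
        score = b0 + float(z @ coef)
        probs[i] = 1.0 / (1.0 + math.exp(-score))
    return FrameTrack(centers / w.rate, probs, step / w.rate, TrackKind.CREAK)


def train_creak_detector(
    n_clips: int = 40, seed: int = 7, lam: float = 0.01
) -> dict[str, object]:
    """Refit the creak combiner from freshly generated labelled frames.

    Used once to produce the frozen CREAK_MODEL coefficients and by tests
    that audit the training procedure; routine detection uses the shipped
    constants.
    """
    from . import classify, synthgen  # local import: synthgen is a sibling layer

    rng = np.random.default_rng(seed)
    feats, labels = [], []

    def harvest(wave: Waveform, truth, want_creak: bool) -> None:
        for t, is_creak, is_voiced in zip(truth.times, truth.creak, truth.voiced):
            if t < 0.08 or t > wave.duration - 0.08 or not is_voiced:
                continue
            if bool(is_creak) != want_creak:
                continue
            feats.append(creak_features(wave, float(t)).as_array())
            labels.append(1.0 if want_creak else -1.0)

    for _ in range(n_clips):
        modal = synthgen.VoiceSpec(
            f0_contour=float(rng.uniform(80, 250)),
            jitter=float(rng.uniform(0.5, 3.0)),
            shimmer=float(rng.uniform(1.0, 5.0)),
            snr=float(rng.uniform(15, 40)),
            duration=0.6,
            seed=int(rng.integers(2**31)),
        )
        harvest(*synthgen.synth_voice(modal), want_creak=False)
        creaky = synthgen.VoiceSpec(
            f0_contour=120.0,
            snr=float(rng.uniform(15, 40)),
            creak_segments=((0.0, 0.6),),
            duration=0.6,
            seed=int(rng.integers(2**31)),
        )
        harvest(*synthgen.synth_voice(creaky), want_creak=True)

    # noise and silence frames are negatives: no pulses, no creak evidence
    for _ in range(n_clips // 2):
        noise = Waveform(rng.standard_normal(int(0.4 * ANALYSIS_RATE)) * 0.05, ANALYSIS_RATE)
        for t in np.arange(0.08, noise.duration - 0.08, 0.02):
            feats.append(creak_features(noise, float(t)).as_array())
            labels.append(-1.0)
    feats.append(np.zeros(4))
    labels.append(-1.0)

    X = np.asarray(feats)
    y = np.asarray(labels)
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale[scale == 0] = 1.0
    model = classify.fit_l1_logistic((X - mean) / scale, y, lam)
    return {
        "feature_mean": mean,
        "feature_scale": scale,
        "coef": model.beta,
        "intercept": model.beta0,
    }


# ---------------------------------------------------------------------------
# Vowel perturbation measures


def hnr_from_r(r: float) -> float:
    """Harmonics-to-noise ratio in dB from the normalized autocorrelation peak."""
    r = min(max(r, 1e-12), 1.0 - 1e-12)
    return 10.0 * math.log10(r / (1.0 - r))


def _refined_peaks(x: np.ndarray, distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Positive peaks with parabolic sub-sample position/height refinement."""
    idx, _ = find_peaks(x, distance=distance, height=0.25 * x.max())
    idx = idx[(idx > 0) & (idx < len(x) - 1)]
    pos = idx.astype(float)
    height = x[idx].astype(float)
    for i, k in enumerate(idx):
        denom = x[k - 1] - 2 * x[k] + x[k + 1]
        if denom < 0:
            delta = 0.5 * (x[k - 1] - x[k + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            pos[i] = k + delta
            height[i] = x[k] - 0.25 * (x[k - 1] - x[k + 1]) * delta
    return pos, height


def perturbation_measures(
    w: Waveform,
    fmin: float = DEFAULT_F0_RANGE_HZ[0],
    fmax: float = 400.0,
    center_s: float = 0.5,
    lh_cut_hz: float = LH_RATIO_CUT_HZ,
) -> PerturbationSet:
    """Jitter, shimmer, HNR and low-high spectral ratio of a sustained vowel.

    Measures use only the center `center_s` seconds, avoiding onset/offset
    instability.  Jitter(local) = mean |Ti − Ti−1| / mean Ti × 100 over
    consecutive cycle lengths; shimmer(local) is the analogue on cycle peak
    amplitudes.  HNR converts the normalized autocorrelation peak r to
    10·log10(r/(1−r)).  Fewer than 10 detected cycles → all measures NaN.
    """
    rate = w.rate
    if w.duration < center_s:
        return MISSING_PERTURBATION
    mid = len(w.samples) // 2
    half = int(center_s * rate / 2)
    seg = w.samples[mid - half : mid + half]
    if not np.any(seg):
        return MISSING_PERTURBATION
    z = seg - seg.mean()

    lag_lo, lag_hi = int(rate / fmax), int(rate / fmin)
    nfft = 1 << int(math.ceil(math.log2(2 * len(z))))
    ac = np.fft.irfft(np.abs(np.fft.rfft(z, nfft)) ** 2, nfft)
    if ac[0] <= 0:
        return MISSING_PERTURBATION
    norm = ac[: lag_hi + 1] / ac[0]
    # unbias the rectangular-truncation taper before reading off r
    norm *= len(z) / (len(z) - np.arange(lag_hi + 1))
    t0 = lag_lo + int(np.argmax(norm[lag_lo : lag_hi + 1]))
    r = float(np.clip(norm[t0], 0.0, 1.0))

    pos, height = _refined_peaks(z, distance=max(2, int(0.7 * t0)))
    if len(pos) < 10:
        return MISSING_PERTURBATION
    periods = np.diff(pos)
    # discard obviously broken cycles (missed or doubled peaks)
    ok = (periods > 0.5 * t0) & (periods < 1.7 * t0)
    periods = periods[ok]
    if len(periods) < 9:
        return MISSING_PERTURBATION
    jitter = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods) * 100.0)
    amps = height[1:][ok]
    shimmer = float(np.mean(np.abs(np.diff(amps))) / np.mean(amps) * 100.0)

    freqs, psd = welch(z, fs=rate, nperseg=min(4096, len(z)))
    low = float(np.sum(psd[freqs < lh_cut_hz]))
    high = float(np.sum(psd[freqs >= lh_cut_hz]))
    lh = 10.0 * math.log10(max(low, 1e-280) / max(high, 1e-280))

    return PerturbationSet(jitter, shimmer, hnr_from_r(r), lh)
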