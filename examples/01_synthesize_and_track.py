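"""Synthesize sustained vowels and read off their frame-level measures.

Three 3-second /a/-like vowels at 120 Hz are rendered from the glottal
pulse-train model, each perturbed in exactly one way — 2 % cycle-length
jitter, 3 % cycle-amplitude shimmer, or additive noise at 25 dB SNR — and
analyzed with the cross-correlation F0 tracker (40 ms window, 3.3 ms
step), the cepstral peak prominence contour (40.96 ms window, 10.24 ms
step), and the cycle-level perturbation measures from the center 500 ms.
"""

import numpy as np

from adhf_voice import (
    VoiceSpec,
    cpp_track,
    perturbation_measures,
    synth_voice,
    track_f0,
)

base = dict(f0_contour=120.0, duration=3.0, seed=42)

jittery, _ = synth_voice(VoiceSpec(jitter=2.0, **base))
shimmery, _ = synth_voice(VoiceSpec(shimmer=3.0, **base))
noisy, _ = synth_voice(VoiceSpec(snr=25.0, **base))

f0 = track_f0(noisy)
voiced = f0.values[f0.values > 0]
print(f"true F0           : 120.0 Hz")
print(f"tracked median F0 : {np.median(voiced):.1f} Hz "
      f"({len(voiced)}/{len(f0)} frames voiced, noisy vowel)")
print(f"jitter recovered  : {perturbation_measures(jittery).jitter_local:.2f} %"
      "  (2.0 % injected)")
print(f"shimmer recovered : {perturbation_measures(shimmery).shimmer_local:.2f} %"
      "  (3.0 % injected)")
print(f"HNR               : {perturbation_measures(noisy).hnr:.1f} dB"
      "  (25 dB SNR injected)")
print(f"mean CPP, clean   : {np.nanmean(cpp_track(jittery).values):.1f} dB")
print(f"mean CPP, noisy   : {np.nanmean(cpp_track(noisy).values):.1f} dB")
print()
print("Each measure recovers the one perturbation injected into its vowel;")
print("CPP drops when noise makes the voice less periodic (less 'healthy').")
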