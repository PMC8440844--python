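"""Subglottal-pressure reference from intraoral pressure.

During /p/ occlusions the vocal tract is sealed and intraoral pressure
equilibrates with the driving pressure; interpolating the plateaus flanking
each vowel gives a non-invasive subglottal pressure estimate.  The example
builds a synthetic six-syllable /p/-vowel string and recovers the plateau
value, with and without measurement noise.
"""

from voxphys.features import iop_reference_pressure
from voxphys.pipeline import trapezoid_iop_train

fs = 2000.0
clean = trapezoid_iop_train(n_syllables=6, plateau=8.0, fs=fs)
print(f"clean trapezoid train  -> {iop_reference_pressure(clean, fs):.2f} cm H2O "
      "(truth 8.00)")

noisy = trapezoid_iop_train(n_syllables=6, plateau=8.0, fs=fs, noise_rms=0.8, seed=1)
print(f"noisy (SNR ~20 dB)     -> {iop_reference_pressure(noisy, fs):.2f} cm H2O")

mixed = trapezoid_iop_train(n_syllables=5, plateau=[7.0, 9.0, 8.0, 8.0, 8.0, 8.0], fs=fs)
print(f"mixed plateaus 7/9/8.. -> {iop_reference_pressure(mixed, fs):.2f} cm H2O "
      "(pairwise means of the three middle syllables)")
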