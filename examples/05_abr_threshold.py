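"""ABR threshold detection and group threshold shift.

Simulates level series (0-120 dB in 5 dB steps) for control-like and
hearing-impaired-like animals, detects each threshold with the
peak-to-peak vs noise-SD criterion, and summarizes the shift.
"""

import numpy as np

import ribbonphys as rp
from ribbonphys import abr

rng = np.random.default_rng(5)

def animal(threshold_db):
    series = rp.synth.simulate_abr_series(threshold_db, growth_rate=0.1, noise_sd=0.05, seed=rng)
    return abr.detect_threshold(series, criterion_sd=6.0).threshold

control = {"click": [animal(40) for _ in range(6)]}
impaired = {"click": [animal(75) for _ in range(6)]}
print("control thresholds (dB): ", control["click"])
print("impaired thresholds (dB):", impaired["click"])

shift = abr.threshold_shift(control, impaired)
row = shift.iloc[0]
print(f"threshold shift: {row['shift_db']:.1f} +/- {row['sem']:.1f} dB (truth 35)")
# An upward shift means louder sounds are needed to evoke a detectable
# brainstem response, i.e. impaired hearing.
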