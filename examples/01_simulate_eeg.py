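"""Generate synthetic low-density EEG and inspect its spectral content.

The clean signal mixes four band-limited sources (1.00-3.91, 3.91-7.81,
7.81-15.62, 15.62-31.25 Hz) through smooth scalp patterns onto a
12-electrode 10-20 layout, plus white sensor noise.
"""

import numpy as np
from scipy import signal as sps

from eegclean import SimSpec, simulate_clean_eeg

rec = simulate_clean_eeg(SimSpec(seed=0, duration_s=60.0))
print(f"channels: {rec.labels}")
print(f"fs = {rec.fs} Hz, duration = {rec.duration} s")
print(f"RMS per channel (uV): {np.round(rec.data.std(axis=1), 1)}")

f, p = sps.welch(rec.data, rec.fs, nperseg=2048, axis=1)
pooled = p.mean(axis=0)
for lo, hi in [(1.0, 3.91), (3.91, 7.81), (7.81, 15.62), (15.62, 31.25), (45.0, 100.0)]:
    sel = (f >= lo) & (f <= hi)
    print(f"mean PSD {lo:6.2f}-{hi:6.2f} Hz: {pooled[sel].mean():8.3f} uV^2/Hz")

# The four source bands carry orders of magnitude more power than the
# 45-100 Hz floor: the generator produces band-limited brain-like rhythms
# over a flat sensor-noise background, reproducible from the seed.
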