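"""Correct blink and EMG artifacts by wavelet thresholding.

Each channel is decomposed with a stationary coif4 transform at depth 10;
per-level empirical-Bayes hard thresholds isolate the large, sparse
coefficients as an artifact timeseries, which is subtracted. Because the
method is per-channel it behaves identically at any channel density.
"""

import numpy as np

from eegclean import (
    ArtifactSpec,
    SimSpec,
    evaluate_recovery,
    inject_artifact,
    percent_variance_retained,
    simulate_clean_eeg,
    wavelet_correct,
)

clean = simulate_clean_eeg(SimSpec(seed=4, duration_s=30.0))
cont, blink = inject_artifact(
    clean, ArtifactSpec(kind="blink", amplitude=150.0, rate_hz=0.3, seed=5)
)
cont, _ = inject_artifact(
    cont,
    ArtifactSpec(kind="emg_burst", amplitude=50.0, rate_hz=0.1,
                 target_channels=["F3", "F4", "T7", "T8"], seed=6),
)

corrected = wavelet_correct(cont)

before = evaluate_recovery(clean, cont)
after = evaluate_recovery(clean, corrected)
print(f"log-PSD error (1-35 Hz) before correction: {before['log_psd_error']:.3f}")
print(f"log-PSD error (1-35 Hz) after  correction: {after['log_psd_error']:.3f}")
print(f"broadband r to ground truth: {before['broadband_r']:.3f} -> {after['broadband_r']:.3f}")
print(f"percent variance retained: {percent_variance_retained(cont, corrected):.1f}%")

i = clean.labels.index("F3")
mask = np.abs(blink[i]) > 20
residual = np.abs(corrected.data[i, mask] - clean.data[i, mask]).max()
print(f"F3 blink peak {np.abs(blink[i]).max():.0f} uV -> residual {residual:.1f} uV")

# The correction moves the contaminated spectrum back onto the ground
# truth (smaller log-PSD error, higher r) while the blink residual drops
# to a small fraction of its injected amplitude.
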