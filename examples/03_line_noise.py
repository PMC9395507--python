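"""Remove a 60 Hz mains tone without touching neighbouring frequencies.

A deterministic sinusoid is fitted per sliding window by multitaper
regression (F-test gated), its amplitude smoothed across windows, and
subtracted. The QC metric reports narrowband pre/post correlations: low
at the line frequency (much was removed), high at the neighbours.
"""

import numpy as np
from scipy import signal as sps

from eegclean import (
    ArtifactSpec,
    LineNoiseParams,
    SimSpec,
    inject_artifact,
    linenoise_qc,
    remove_line_noise,
    simulate_clean_eeg,
)

clean = simulate_clean_eeg(SimSpec(seed=1, duration_s=60.0))
cont, _ = inject_artifact(
    clean, ArtifactSpec(kind="line_sine", amplitude=20.0, params={"freq_hz": 60.0})
)
post = remove_line_noise(cont, LineNoiseParams(target_freqs=[60.0]))

f, p_pre = sps.welch(cont.data, cont.fs, nperseg=2048, axis=1)
_, p_post = sps.welch(post.data, post.fs, nperseg=2048, axis=1)
i60 = np.argmin(np.abs(f - 60.0))
print(f"60 Hz attenuation: {10 * np.log10(p_pre[:, i60].mean() / p_post[:, i60].mean()):.1f} dB")

for freq, r in linenoise_qc(cont, post, 60.0).items():
    print(f"r pre/post at {freq:4.0f} Hz: {r:6.3f}")

# r collapses only at 59-61 Hz; at +/-5 Hz it stays ~1.0, confirming the
# removal is confined to the targeted frequency.
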