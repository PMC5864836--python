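"""EGG band power vs manometric motility index, before and after cleaning.

Simulates a coupled scenario: a shared contraction envelope modulates
both the EGG slow-wave amplitude and the antral pressure peaks, while
motion artifacts corrupt the EGG.  The correlation between windowed EGG
power and the motility index improves once artifacts are removed.
"""

from eggkit import (
    SynthConfig,
    compute_spectrogram,
    correlate_egg_manometry,
    egg_features,
    motility_index,
    remove_artifacts,
    simulate_coupled_manometry,
    simulate_egg,
)

cfg = SynthConfig(
    duration_s=7200, envelope_sigma=0.5, envelope_timescale_s=600,
    artifact_rate_per_hour=15, seed=2,
)
sig, truth = simulate_egg(cfg)
pressure = simulate_coupled_manometry(truth)
mi = motility_index(pressure)            # ln(area above 9 mmHg) per window

power_raw = egg_features(compute_spectrogram(sig)).band_power_db
power_clean = egg_features(
    compute_spectrogram(remove_artifacts(sig).cleaned)
).band_power_db

raw = correlate_egg_manometry(power_raw, mi)
clean = correlate_egg_manometry(power_clean, mi)

print(f"windows                  : {raw.n_windows}")
print(f"r  raw EGG power vs MI   : {raw.r:6.2f}  (p = {raw.p_value:.2e})")
print(f"r  cleaned power vs MI   : {clean.r:6.2f}  (p = {clean.p_value:.2e})")
# Artifact bursts inflate raw band power in arbitrary windows and mask
# the physiological coupling; cleaning recovers it.
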