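"""Measure delta-phase / high-gamma-amplitude coupling with the modulation index.

The MI is the normalized KL distance of the phase-binned amplitude
distribution from uniform: 0 for no coupling, 1 when all amplitude falls in
one 18-degree phase bin. We sweep the injected coupling strength and show
the measured MI rank-orders it.
"""

import pandas as pd

from strokesig.events import EVENT_COLUMNS
from strokesig.pac import (
    bin_amplitude_by_phase,
    instantaneous_amplitude,
    instantaneous_phase,
    modulation_index,
)
from strokesig.synthetic import SyntheticConfig, generate_lfp

NO_EVENTS = pd.DataFrame(columns=EVENT_COLUMNS)

print("coupling strength -> measured MI")
for strength in (0.0, 0.25, 0.5, 0.75, 1.0):
    cfg = SyntheticConfig(
        n_arrays=1,
        channels_per_array=1,
        duration_s=30.0,
        pac_strength=strength,
        gamma_event_gain=1.0,
        seed=4,
    )
    x = generate_lfp(cfg, NO_EVENTS)[0].astype(float)
    phase = instantaneous_phase(x, cfg.fs_lfp)          # delta band, degrees
    amp = instantaneous_amplitude(x, cfg.fs_lfp)        # high-gamma envelope
    mi = modulation_index(bin_amplitude_by_phase(phase, amp))
    print(f"  {strength:4.2f} -> {mi:.4f}")
print("MI increases monotonically with the injected coupling.")
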