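"""Run the training-less spectral grasp decoder on a synthetic session.

The decoder watches mean 100-500 Hz band power over the most neuromodulated
channels and issues "close" when the feature exceeds 10, and "open" when it
falls back into the 0.5-3 baseline range, with hysteresis in between. We
compare its commands with the planted closing times.
"""

import numpy as np

from strokesig.decoding import threshold_decoder
from strokesig.spectral import mean_band_power, sliding_psd
from strokesig.spikes import neuromodulation_index
from strokesig.synthetic import SyntheticConfig, generate_arat_session

cfg = SyntheticConfig(
    n_arrays=1,
    channels_per_array=16,
    duration_s=180.0,
    n_clean_closings=8,
    n_responsive=8,
    seed=9,
)
bundle, truth = generate_arat_session(cfg)

_, top_channels = neuromodulation_index(bundle.spikes, bundle.duration_s)
series = sliding_psd(bundle.lfp[top_channels], bundle.fs_lfp, 1.0, 0.5,
                     band=(100.0, 500.0), resolution_hz=1.0)
times, feature = mean_band_power(series)
trace = threshold_decoder(times, feature)

close_cmds = np.array([t for t, c in trace.commands if c == "close"])
planted = truth.planted_events.query("event_type == 'close'").onset_s.to_numpy()
matched = sum(np.any(np.abs(close_cmds - t) <= 1.0) for t in planted)
print(f"feature range: baseline ~{np.median(feature):.2f}, peak {feature.max():.1f}")
print(f"close commands at: {np.round(close_cmds, 2)}")
print(f"planted closings at: {np.round(planted, 2)}")
print(f"{matched}/{planted.size} planted closings matched within 1 s")
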