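"""Generate a small synthetic grasp session and look at what is inside it.

The generator plants everything the analysis chain later has to find: valid
aperture closings/openings, event-locked high-gamma on the LFP, and a subset
of spiking channels that modulate before each closing. The ground-truth
object records where all of it is.
"""

import numpy as np

from strokesig.synthetic import SyntheticConfig, generate_arat_session

cfg = SyntheticConfig(
    n_arrays=2,
    channels_per_array=8,
    duration_s=90.0,
    n_clean_closings=5,
    n_pause_resume=1,
    n_responsive=6,
    seed=0,
)
bundle, truth = generate_arat_session(cfg)

print(f"LFP: {bundle.lfp.shape[0]} channels x {bundle.lfp.shape[1]} samples "
      f"at {bundle.fs_lfp:g} Hz")
print(f"aperture trace: {bundle.aperture.size} samples at {bundle.fs_aperture:g} Hz, "
      f"range {bundle.aperture.min():.1f}-{bundle.aperture.max():.1f}% open")
print(f"spike trains: {len(bundle.spikes)} channels, "
      f"mean rate {np.mean([len(s) for s in bundle.spikes]) / cfg.duration_s:.1f} sp/s")
print(f"planted events:\n{truth.planted_events.to_string(index=False)}")
print(f"planted responsive channels: {len(truth.responsive_channel_ids)} of "
      f"{bundle.lfp.shape[0]}")
# Re-running with the same seed reproduces the session bit for bit.
bundle2, _ = generate_arat_session(cfg)
print("deterministic:", np.array_equal(bundle.lfp, bundle2.lfp))
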