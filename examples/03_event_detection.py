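"""Detect valid hand closing and opening events from an aperture trace.

A closing is valid only if it starts from a nearly open hand (>= 80%
aperture) and reaches at most 30% aperture; openings mirror this. The
generator plants clean events plus deliberately tricky ones: pause-and-
resume closings (still valid; onset is the last sweep), stalled closings
(never reach 30%, invalid), and closings starting from a half-open hand
(invalid).
"""

from strokesig.events import detect_events
from strokesig.synthetic import SyntheticConfig, generate_aperture_trace

cfg = SyntheticConfig(
    duration_s=150.0,
    n_clean_closings=3,
    n_pause_resume=2,
    n_stalled=2,
    n_low_start=2,
    inter_block_hold_s=4.0,
    seed=11,
)
aperture, planted = generate_aperture_trace(cfg)

detected = detect_events(aperture, 20.0)
print("planted valid events:")
print(planted.to_string(index=False))
print("\ndetected events:")
print(detected.to_string(index=False))

n_close = (detected.event_type == "close").sum()
n_plant = (planted.event_type == "close").sum()
print(f"\n{n_close} closings detected vs {n_plant} planted valid closings "
      "(stalled and low-start blocks are correctly rejected)")
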