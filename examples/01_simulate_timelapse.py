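"""Generate a seeded synthetic time-lapse of one nucleus and inspect its truth.

The generator renders diffraction-limited repair-protein foci (2D Gaussians)
inside an elliptical nucleus, moves them by Brownian motion, lets them appear
and disappear, grows their amplitude, bleaches the field and adds shot + read
noise. The returned ground truth lists every focus per frame.
"""

import focitrack as ft

cfg = ft.SimConfig(n_frames=20, birth_rate=0.2, death_prob=0.03, seed=1)
stack, truth = ft.simulate_timelapse(cfg)

print(f"stack: {stack.shape[0]} frames of {stack.shape[1]}x{stack.shape[2]} px")
print(f"foci per frame: {[int(c) for c in truth.counts_per_frame()]}")
durations = sorted(truth.durations().values(), reverse=True)
print(f"longest true track durations (min): {durations[:5]}")
# Counts drift up/down as foci are born (0.2/frame) and die (3%/frame);
# durations are (death - birth) x 20 min, the quantity the tracker must recover.
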