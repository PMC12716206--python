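"""Slow-axis waveform and the scan-time arithmetic of line skipping.

Shows the modified Y-signal (one dwell per scanned line, steeper ramps
across skipped runs instead of creep-inducing steps) and the
proportional timing model: a 19 min 19 s full scan at 30% masking takes
13 min 31 s.
"""

import partialscan as ps

lm = ps.random_line_mask(256, 0.30, seed=3)
sig = ps.build_y_signal(lm, line_period=4.53)
print(f"{sig.n_segments} dwell segments (one per scanned line), "
      f"total {sig.total_time:.0f} s")
print(f"y advances monotonically from {sig.y_positions[0]:.0f} "
      f"to {sig.y_positions[-1]:.0f} line pitches")

tm = ps.TimingModel(full_scan_time=19 * 60 + 19)
t = ps.partial_scan_time(lm, tm)
print(f"full scan {tm.full_scan_time:.0f} s -> partial scan {t} s "
      f"({t // 60} min {t % 60} s), "
      f"{100 * (1 - t / tm.full_scan_time):.1f}% time saving")
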