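"""Generate a synthetic SICM-like scene and a 30% line mask.

Builds one 96x96 topography frame (cell bodies + neurite-like ridges +
line/pixel noise), normalizes it, and draws a random line mask skipping
30% of the slow-axis lines.  Prints the scene statistics and the exact
masked-line count implied by the rounding rule.
"""

import partialscan as ps

scene = ps.generate_scene(ps.SceneParams(seed=7))
print(f"scene: {scene.shape[0]}x{scene.shape[1]} px, "
      f"heights {scene.values.min():.2f}..{scene.values.max():.2f} um")

norm = ps.normalize(scene)
print(f"normalized to [0,1], recorded span {norm.norm_params}")

lm = ps.random_line_mask(norm.n_rows, 0.30, seed=1)
print(f"mask: {lm.n_skipped}/{lm.n_lines} lines skipped "
      f"(round_half_up(0.30*{lm.n_lines}) = {ps.round_half_up(0.3 * lm.n_lines)}); "
      f"borders scanned: {bool(lm.keep[0] and lm.keep[-1])}")
print(f"longest run of consecutive skips: {lm.max_run()}")

# Controlled patterns hit the same count deterministically
for pattern in ("fixed_distance", "geometric"):
    plm = ps.patterned_line_mask(lm.n_lines, 0.30, pattern)
    print(f"{pattern}: {plm.n_skipped} skipped lines")
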