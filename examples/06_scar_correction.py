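"""Scar detection and correction.

Plants full-row scars (feedback-overshoot-like offsets) into a clean
scene, recovers the scar mask with the robust row detector, and corrects
the scars with median line correction.  Prints detection accuracy and
the residual error on scarred rows.  (With a trained Partial-CNN,
`reconstruct` on the extracted mask replaces the median step — see
scripts/acceptance.py for the head-to-head comparison.)
"""

import numpy as np

import partialscan as ps

raw = ps.generate_scene(ps.SceneParams(seed=21))
scarred, truth = ps.add_scars(raw, ps.ScarSpec(n_scars=8, seed=4))
print(f"planted scars at rows {sorted(truth.skipped_rows.tolist())}")

detected = ps.extract_scar_mask(scarred)
print(f"detected rows          {sorted(detected.skipped_rows.tolist())}")

corrected = ps.median_line_correct(scarred, detected)
rows = truth.skipped_rows
rms_before = np.sqrt(np.mean((scarred.values[rows] - raw.values[rows]) ** 2))
rms_after = np.sqrt(np.mean((corrected.values[rows] - raw.values[rows]) ** 2))
print(f"RMS error on scarred rows: {rms_before:.3f} um -> {rms_after:.3f} um "
      f"after median line correction")
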