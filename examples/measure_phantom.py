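"""Measure lesion contrast on a synthetic recombined-view phantom.

Builds an early/late image pair with a programmed lesion (CE_early 0.5,
CE_late 0.4 over a background level of 1000), measures the ROI statistics
and derives CE, %RSD and the kinetic pattern.
"""

import cemquant as cq

case = cq.generate_phantom(
    shape=(256, 256), sb_level=1000.0,
    peak_early=0.5, peak_late=0.4,
    noise_scale=0.005, seed=42,
)

ce = {}
for view, image in (("early", case.early_image), ("late", case.late_image)):
    s_a, s_b = cq.measure_roi(image, case.lesion_mask, case.background_mask)
    ce[view] = cq.compute_ce(s_a, s_b)
    print(f"{view:5s} view: Sa={s_a:7.1f}  Sb={s_b:7.1f}  CE={ce[view]:.4f}")

rsd = cq.compute_rsd(ce["early"], ce["late"])
pattern = cq.classify_pattern(rsd)
print(f"%RSD = {rsd:.1f}  ->  kinetic pattern: {pattern.value}")
print("A %RSD below -10 marks wash-out kinetics, the pattern typical of "
      "malignancy; the small CE excess over the programmed 0.5/0.4 is the "
      "upward bias of the ROI maximum under noise.")
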