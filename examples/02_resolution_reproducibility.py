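"""Cross-resolution reproducibility of the calcium segmentation.

Generates an ensemble of cohort-scale phantoms at 0.625 mm, down-samples
each CT (and artery mask) to 1.25 mm, reruns the identical HU-window
segmentation and correlates the two volume measurements — the in-silico
analogue of re-scanning the same participants at a coarser protocol.
"""

from calcmorph import evaluation as ev

res = ev.resolution_reproducibility(n_phantoms=25, seed=7)

print(f"phantoms                  : {res['n']}")
print(f"mean volume at 0.625 mm   : {res['mean_volume_mm3']:.1f} mm3")
print(f"mean |volume difference|  : {res['mean_abs_diff_mm3']:.2f} mm3")
print(f"Pearson r across scales   : {res['pearson']:.4f}")
print()
print("High correlation means the 130-500 HU segmentation ranks deposit")
print("burden consistently across acquisition resolutions; the absolute")
print("difference shows the per-deposit cost of the coarser grid.")
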