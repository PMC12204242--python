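"""Measure a phantom patient end to end and compare with the ground truth.

Uses the exact rasterized interior masks (oracle mode), so the differences
shown are pure measurement-geometry error, not segmentation error.
"""

from pectus.indices import measure_patient
from pectus.phantom import PhantomParams, StackParams, make_phantom_stack
from pectus.slices import select_target

sp = StackParams(
    base=PhantomParams(dent_depth=3.5, dent_center_offset=1.2, noise_sd=6.0, seed=7),
    depth_profile=(0.3, 0.55, 0.8, 1.0, 0.8, 0.55, 0.3),
)
slices, masks, gt = make_phantom_stack(sp)

selection = select_target(slices)           # deepest slice from the outer contour
report = measure_patient(slices, masks, selection)
h = report.headline

print(f"target slice        {selection.target_index} (truth {gt.deepest_slice})")
print(f"per-slice depth cm  {[round(d, 2) for d in selection.per_slice_depth_cm]}")
print(f"Haller index        {h.haller:.3f}  (truth {gt.haller:.3f}, {h.severity})")
print(f"Correction index    {h.correction_pct:.1f} % (truth {gt.correction_pct:.1f} %)")
print(f"Asymmetry index     {h.asymmetry:.3f}  (truth {gt.asymmetry:.3f})")
print("\nIndices on every neighborhood slice:")
for iset in report.per_slice:
    mark = "*" if iset.slice_index == selection.target_index else " "
    print(f"  slice {iset.slice_index}{mark} HI {iset.haller:5.2f}  "
          f"CI {iset.correction_pct:5.1f} %  AI {iset.asymmetry:.3f}")
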