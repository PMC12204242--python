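"""The deepest-slice selection procedure, slice by slice.

For each axial slice the outer body contour is traced, a tangent line is
drawn across the two anterior chest crests, and the depression depth is the
perpendicular drop of the deepest sternal point below that line.  The slice
with the largest depth becomes the measurement target.
"""

from pectus.phantom import PhantomParams, StackParams, make_phantom_stack
from pectus.slices import depression_depth, outer_body_contour, select_target

sp = StackParams(
    base=PhantomParams(dent_depth=4.0, noise_sd=6.0, seed=3),
    depth_profile=(0.2, 0.45, 0.7, 0.9, 1.0, 0.85, 0.6, 0.35, 0.2),
)
slices, _, gt = make_phantom_stack(sp)

print("slice  depth_cm")
for i, sl in enumerate(slices):
    depth, crest_l, crest_r, deepest = depression_depth(outer_body_contour(sl))
    print(f"  {i}     {depth:5.2f}")

sel = select_target(slices, k=3)
print(f"\ntarget slice: {sel.target_index} (ground truth {gt.deepest_slice})")
print(f"measurement neighborhood (inclusive +/-3): {sel.neighborhood}")
sel6 = select_target(slices, k=3, literal_six=True)
print(f"literal six-slice mode (target excluded):  {sel6.neighborhood}")
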