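"""Generate a synthetic phantom patient and print its analytic ground truth.

The phantom is an elliptical thoracic cross-section with a Gaussian anterior
depression and a circular vertebral protrusion; every severity index has a
closed-form value, which is what the rest of the pipeline is tested against.
"""

from pectus.phantom import PhantomParams, StackParams, analytic_indices, make_phantom_stack

params = PhantomParams(
    transverse_semiaxis=10.0,   # inner transverse half-diameter, cm
    ap_semiaxis=6.0,            # inner anteroposterior half-diameter, cm
    dent_depth=4.0,             # sternal depression depth, cm
    dent_center_offset=1.0,     # depression shifted 1 cm toward patient left
    dent_width=3.0,
    spine_radius=1.5,
    noise_sd=6.0,
    seed=42,
)
gt = analytic_indices(params)
print(f"Haller index      {gt.haller:.3f}   (transverse {gt.transverse_cm:.1f} cm / cd {gt.cd_cm:.2f} cm)")
print(f"Correction index  {gt.correction_pct:.1f} %  (ab {gt.ab_cm:.2f} cm, cd {gt.cd_cm:.2f} cm)")
print(f"Asymmetry index   {gt.asymmetry:.3f}   (R {gt.R_cm:.2f} cm / L {gt.L_cm:.2f} cm)")

# A per-patient axial series: the depression depth varies across slices with
# a unique maximum, which defines the slice the indices are measured on.
stack = StackParams(base=params, depth_profile=(0.3, 0.6, 1.0, 0.6, 0.3))
slices, masks, stack_gt = make_phantom_stack(stack)
print(f"\nStack of {len(slices)} slices; deepest depression on slice "
      f"{stack_gt.deepest_slice} (0-based).")
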