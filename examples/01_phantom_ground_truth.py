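"""Generate spheroid phantoms and inspect their analytic ground truth.

A hollow phantom mimics an intact duct bilayer (nuclei shell around an
open lumen); a filled phantom mimics DCIS-like luminal filling.  The
expected cell/body volume ratio is closed-form: 1 - (1 - f)(r/R)^3.
"""

import lumenfill as lf

for name, spec in [("hollow (control)", lf.hollow_control_spec(seed=1)),
                   ("filled (induced)", lf.filled_induced_spec(seed=1))]:
    stack, truth = lf.generate_phantom(spec)
    print(f"{name}: R = {spec.outer_radius_um} um, lumen = {spec.lumen_radius_um} um, "
          f"fill = {spec.fill_fraction}")
    print(f"  stack {stack.shape} voxels at pitch {stack.pitch} um")
    print(f"  analytic body volume : {truth.true_body_volume_um3:9.0f} um^3")
    print(f"  analytic cell volume : {truth.true_cell_volume_um3:9.0f} um^3")
    print(f"  expected cell/body   : {truth.true_ratio:.3f}")
    print(f"  rendered nuclei union: {truth.rendered_cell_volume_um3:9.0f} um^3 "
          "(voxel-counted; nuclei do not tile the shell completely)")

# The expected ratio of a hollow shell depends only on the radii:
spec = lf.hollow_control_spec()
print(f"\nhollow expected ratio = 1 - (12/20)^3 = {lf.expected_ratio(spec):.3f}")
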