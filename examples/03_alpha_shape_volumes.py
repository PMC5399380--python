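"""Alpha-shape volumetrics: cell volume, body volume, filling ratio.

The same point cloud yields two triangulated bodies: a small alpha
(3 x max pitch = 6 um) hugs the nuclei and excludes the lumen — the cell
volume; an effectively infinite alpha spans the lumen — the spheroid
body.  Their ratio is the luminal-filling statistic.
"""

import lumenfill as lf

config = lf.RunConfig(manifest="unused")

for name, spec in [("hollow", lf.hollow_control_spec(seed=5)),
                   ("filled", lf.filled_induced_spec(seed=5))]:
    stack, truth = lf.generate_phantom(spec)
    result = lf.analyze_stack(stack, config, spheroid_id=name)
    print(f"{name} phantom:")
    print(f"  cell volume: {result.cell_volume_um3:8.0f} um^3 (alpha = 6 um)")
    print(f"  body volume: {result.body_volume_um3:8.0f} um^3 (alpha -> inf)")
    print(f"  ratio      : {result.ratio:.3f}   (analytic expectation "
          f"{truth.true_ratio:.3f})")

print("\nA hollow bilayer sits near the shell fraction 0.784; a filled "
      "lumen drives the ratio toward 1.")
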