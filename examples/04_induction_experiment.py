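"""A complete in-silico induction experiment with rescue arm.

Simulates three treatment groups of spheroids — hollow controls, filled
(induced) and hollow rescue (induction + inhibitor) — runs the full
pipeline over the written TIFF stacks, and compares the groups by
one-way ANOVA with Tukey's HSD post-hoc test.
"""

import tempfile
from pathlib import Path

import lumenfill as lf

with tempfile.TemporaryDirectory() as tmp:
    manifest = lf.simulate_experiment(Path(tmp) / "data", n_per_group=6,
                                      include_rescue=True, seed=1)
    report = lf.run_pipeline(lf.RunConfig(manifest=str(manifest),
                                          out_dir=str(Path(tmp) / "out"), seed=1))

    print(report.results[["spheroid_id", "group", "ratio"]]
          .round(3).to_string(index=False))
    print()
    print(report.comparison.summary())
    print("\nThe induced group separates from both hollow arms (p < 0.01, '**'),")
    print("while control vs rescue is indistinguishable — the in-silico analogue")
    print("of filling blocked by an inhibitor.")
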