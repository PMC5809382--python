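"""Run every stage end-to-end and render the run report.

One seeded call executes generation, preconditioning, EFA, PCA, MANOVA,
TPS, stacking, collinearity screening, mixed-model selection and effect
sizes, persisting all artifacts (CSV tables, JSON manifest, log) to the
output directory.
"""

import tempfile

from musselshape import pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = pipeline.RunConfig(outdir=tmp, n_sites=10, n_per_site=12, seed=7)
    pipeline.run_pipeline(config)
    print(pipeline.report(tmp))
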