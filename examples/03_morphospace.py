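"""Build the PCA morphospace and test site and length effects.

Combines the normalized Fourier coefficients of both views into one
feature vector per specimen, decomposes by PCA, reconstructs shapes at
the extremes of PC1, and runs Wilks-lambda MANOVAs for collection site
and shell length.
"""

import numpy as np

from musselshape import morphospace, outline_io, synth
from musselshape.efa import assemble_shape_matrix, efa_forward, efa_normalize

env = synth.generate_environment(15, seed=1)
ds = synth.generate_dataset(env, 20, synth.GeneratorConfig(seed=2))

coeffs = {
    sid: {
        view: efa_normalize(efa_forward(outline_io.orient_outline(o), 7))
        for view, o in views.items()
    }
    for sid, views in ds.outlines.items()
}
model = morphospace.fit_pca(assemble_shape_matrix(coeffs))

print("% variance of the first five shape PCs:")
for j in range(5):
    print(f"  PC{j + 1}: {model.pct_variance[j]:5.1f}%")
# PCs are new shape variables; any point in the space reconstructs to a
# shell outline pair, e.g. the mean shape +/- 3 SD along PC1:
lo_lat, _ = morphospace.reconstruct_at(model, 0, -3.0, 7, 128)
hi_lat, _ = morphospace.reconstruct_at(model, 0, +3.0, 7, 128)
print(f"PC1 -3SD lateral area {abs(lo_lat.signed_area()):.3f} vs "
      f"+3SD {abs(hi_lat.signed_area()):.3f} (normalized units)")

meta = ds.specimens.set_index("specimen_id").loc[model.specimen_ids]
for name, pred in (
    ("site", meta.site_id.to_numpy()),
    ("length", meta.length.to_numpy(dtype=float)),
):
    res = morphospace.manova_wilks(model.scores[:, :10], pred, name)
    print(f"MANOVA {name}: Wilks lambda={res.wilks_lambda:.4f}, "
          f"approx F={res.approx_f:.2f}, p={res.p_value:.3g}")
# small lambda = strong multivariate separation of shape by the predictor
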