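"""Select the ridge penalty by gene-split cross-validation.

Genes (columns) are split into 5 folds; for each candidate lambda the model
is fit on the training genes and scored on the held-out genes by the mean
squared reconstruction error MMSE(lambda). On noiseless data the selection
must fall on lambda = 0 (no bias needed); with noise a positive lambda can
win.
"""

import spotdeconv as sd

for noise in ("none", "poisson"):
    cfg = sd.SimulationConfig(noise_model=noise, seed=3)
    ref, spatial, _ = sd.generate_dataset(cfg)
    ref_pp, spatial_pp = sd.preprocess(*sd.align_genes(ref, spatial))
    solver = sd.SolverConfig(
        learning_rate=0.01, ridge_lambda=sd.DEFAULT_LAMBDA_GRID, n_fold=5, seed=3
    )
    report = sd.cross_validate_lambda(spatial_pp.counts, ref_pp.counts, solver)
    print(f"\nnoise_model={noise}: selected lambda = {report.selected_lambda}")
    print(report.to_frame().round(4).to_string())
# each row is one candidate lambda; the "mean" column is the cross-fold
# average of the held-out-gene reconstruction error, minimized by the winner
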