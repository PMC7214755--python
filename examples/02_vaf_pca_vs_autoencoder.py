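"""Reconstruction quality: PCA vs. the nonlinear autoencoder across latent sizes.

The generator places the data on a curved 2-D manifold in 20-channel space.
PCA, a linear method, needs extra components to cover the curvature; the
autoencoder can follow it with exactly 2 coding units.  VAF (variance
accounted for, %) measures how much signal variance each reconstruction
preserves on held-out test samples.
"""

from dataclasses import replace

from kinlatent import (
    SyntheticSpec,
    TrainingConfig,
    fit_pca,
    forward,
    generate_dataset,
    holdout_split,
    init_model,
    normalize_global_absmax,
    pca_decode,
    pca_encode,
    remove_rest,
    train,
    vaf,
)

spec = SyntheticSpec(
    n_classes=6,
    trials_per_class=3,
    active_duration_s=1.5,
    rest_duration_s=1.0,
    ramp_duration_s=0.4,
    map_kind="nonlinear",
    seed=0,
)
ds = normalize_global_absmax(remove_rest(generate_dataset(spec)))
train_idx, test_idx = holdout_split(ds.n_samples, 0.8, seed=0)
X_train, X_test = ds.X[train_idx], ds.X[test_idx]

pca = fit_pca(X_train)
print(f"{'k':>2}  {'PCA VAF':>8}  {'nAEN VAF':>8}   (test set, %)")
for k in (2, 3, 4, 5, 6):
    pca_vaf = vaf(X_test, pca_decode(pca, pca_encode(pca, X_test, k))).aggregate_vaf
    model = init_model(ds.n_channels, 10, k, "tanh", seed=0)
    trained, _ = train(model, X_train, TrainingConfig(steps=2000))
    ae_vaf = vaf(X_test, forward(trained, X_test)).aggregate_vaf
    print(f"{k:>2}  {pca_vaf:8.2f}  {ae_vaf:8.2f}")
print(
    "\nWith 2 latent dimensions the autoencoder preserves far more variance\n"
    "than 2 principal components; the advantage shrinks as k grows because\n"
    "extra linear components eventually cover the manifold's curvature."
)
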