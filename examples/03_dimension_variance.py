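"""How evenly each method spreads variance across its latent dimensions.

Dimension variance is each latent coordinate's percentage of the total
latent variance; its max-minus-min is the *range*.  PCA orders components
by variance, so its profile drops steeply; the autoencoder's coding units
have no such ordering constraint and share variance more evenly — useful
when each latent coordinate becomes an independent control signal.
"""

from kinlatent import (
    SyntheticSpec,
    TrainingConfig,
    dimension_variance,
    encode,
    fit_pca,
    generate_dataset,
    holdout_split,
    init_model,
    normalize_global_absmax,
    pca_encode,
    remove_rest,
    train,
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
train_idx, _ = holdout_split(ds.n_samples, 0.8, seed=0)

pca = fit_pca(ds.X[train_idx])
for k in (2, 4, 6):
    model = init_model(ds.n_channels, 10, k, "tanh", seed=0)
    trained, _ = train(model, ds.X[train_idx], TrainingConfig(steps=2000))
    p_pca = dimension_variance(pca_encode(pca, ds.X, k))
    p_ae = dimension_variance(encode(trained, ds.X))
    print(f"k={k}")
    print(f"  PCA  profile {[f'{v:5.1f}' for v in p_pca.v_dim]}  range {p_pca.range:5.1f}")
    print(f"  nAEN profile {[f'{v:5.1f}' for v in p_ae.v_dim]}  range {p_ae.range:5.1f}")
print(
    "\nProfiles are percentages summing to 100 within each method/k.\n"
    "A smaller range means variance is spread more evenly across dimensions."
)
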