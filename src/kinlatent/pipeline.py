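"""End-to-end comparison experiment: PCA vs. autoencoder on labeled recordings.

For every participant (a synthetic seed or a recording file) the pipeline
runs the full chain — low-pass filter, REST removal, abs-max normalization,
80/20 holdout — then, for each latent size k, fits PCA and the autoencoder
on the training samples and scores them on:

* **reconstruction**: aggregate VAF on the held-out test samples;
* **dimension variance**: latent variance shares and their range, evaluated
  on the entire dataset (training and testing combined);
* **movement separability** (at k = 2): cross-validated SoftMax accuracy on
  the original 20-D data, each 2-D latent, and each reconstructed 20-D
  space, again on the entire dataset.

Across participants it then runs the rank-statistics layer: a Wilcoxon
signed-rank test on VAF (autoencoder vs. PCA, paired over participant x k),
a Friedman test for the effect of latent size on each method's VAF, and a
post-hoc family of four Bonferroni-adjusted Wilcoxon contrasts (range of
dimension variance AE vs. PCA; separability latent vs. reconstructed for
each method; VAF at k = 2).  The whole run is a deterministic function of
the configuration and its seed.

Note: evaluating VAF on held-out samples but dimension variance and
separability on the full dataset mirrors the study design this pipeline
reproduces; it is a protocol choice, not a leakage-free best practice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .autoencoder import TrainingConfig, encode, forward, init_model, train
from .metrics import (
    LatentRepresentation,
    dimension_variance,
    signal_variance,
    vaf,
)
from .pca import fit_pca, pca_decode, pca_encode
from .preprocess import (
    butterworth_lowpass,
    holdout_split,
    normalize_global_absmax,
    remove_rest,
)
from .recording import read_recording
from .separability import softmax_cv_accuracy
from .stats import bonferroni_adjust, friedman_test, wilcoxon_signed_rank
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger("kinlatent")

PCA_METHOD = "PCA"
AE_METHOD = "nAEN"


class PipelineError(RuntimeError):
    """Raised when an experiment stage fails; names the stage and participant."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one comparison experiment."""

    synthetic_spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    recording_paths: tuple = ()
    n_participants: int = 10
    participant_seeds: tuple = ()
    k_values: tuple = (2, 3, 4, 5, 6)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    hidden_size: int = 10
    filter_cutoff_hz: float = 10.0
    filter_order: int = 1
    zero_phase: bool = True
    holdout_frac: float = 0.8
    separability_folds: int = 5
    separability_k: int = 2
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        n_channels = self.synthetic_spec.n_channels
        if not self.k_values:
            raise PipelineError("k_values must be nonempty")
        for k in self.k_values:
            if not 1 <= k < n_channels:
                raise PipelineError(
                    f"k={k} out of range [1, {n_channels - 1}] for {n_channels} channels"
                )
        if not self.recording_paths and self.n_participants < 1:
            raise PipelineError("need at least one participant")

    def seeds(self) -> list[int]:
        if self.recording_paths:
            return []
        if self.participant_seeds:
            return [int(s) for s in self.participant_seeds]
        return [
            int((self.seed * 1009 + 7919 * i) % 2**31)
            for i in range(self.n_participants)
        ]


@dataclass
class ComparisonReport:
    """JSON-serializable payload of one full experiment."""

    payload: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def vaf_table(self) -> pd.DataFrame:
        """Long-format (participant, method, k, vaf_test) table."""
        rows = []
        for pid, block in self.payload["participants"].items():
            for method, by_k in block["vaf_test"].items():
                for k, value in by_k.items():
                    rows.append(
                        {"participant": pid, "method": method, "k": int(k), "vaf": value}
                    )
        return pd.DataFrame(rows)


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synthetic_spec"] = dataclasses.asdict(config.synthetic_spec)
    d["training"] = dataclasses.asdict(config.training)
    for key in ("recording_paths", "participant_seeds", "k_values"):
        d[key] = list(d[key])
    return d


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0] % 2**31)


def export_latent_scatter(Z: LatentRepresentation, movement_class, trial_id, path):
    """Write a 2-D latent cloud as tidy CSV (dim1, dim2, movement_class, trial_id)."""
    if Z.n_dims != 2:
        raise PipelineError(f"latent scatter export needs exactly 2 dims, got {Z.n_dims}")
    pd.DataFrame(
        {
            "dim1": Z.A[:, 0],
            "dim2": Z.A[:, 1],
            "movement_class": np.asarray(movement_class),
            "trial_id": np.asarray(trial_id, dtype=int),
        }
    ).to_csv(path, index=False, float_format="%.10g")


def _analyze_participant(config: ExperimentConfig, pid: str, rec):
    """Run the per-participant chain; returns the report block and raw latents."""
    stage = "preprocess"
    try:
        rec = butterworth_lowpass(
            rec, config.filter_cutoff_hz, config.filter_order, config.zero_phase
        )
        rec = remove_rest(rec)
        ds = normalize_global_absmax(rec)
        train_idx, test_idx = holdout_split(
            ds.n_samples, config.holdout_frac, seed=_derive_seed(config.seed, 1)
        )
        X, X_train, X_test = ds.X, ds.X[train_idx], ds.X[test_idx]

        block = {
            "signal_variance": signal_variance(X),
            "n_samples": int(ds.n_samples),
            "vaf_test": {PCA_METHOD: {}, AE_METHOD: {}},
            "dimension_variance": {PCA_METHOD: {}, AE_METHOD: {}},
            "separability": {},
        }
        latents_2d = {}

        stage = "pca"
        pca_model = fit_pca(X_train)
        for k in config.k_values:
            z_test = pca_encode(pca_model, X_test, k)
            block["vaf_test"][PCA_METHOD][str(k)] = vaf(
                X_test, pca_decode(pca_model, z_test)
            ).aggregate_vaf
            profile = dimension_variance(pca_encode(pca_model, X, k))
            block["dimension_variance"][PCA_METHOD][str(k)] = {
                "v_dim": profile.v_dim.tolist(),
                "range": profile.range,
            }

        stage = "autoencoder"
        ae_models = {}
        for k in config.k_values:
            model = init_model(
                ds.n_channels,
                config.hidden_size,
                k,
                activation=config.training.activation,
                seed=_derive_seed(config.seed, 2, k),
            )
            trained, _ = train(model, X_train, config.training)
            ae_models[k] = trained
            block["vaf_test"][AE_METHOD][str(k)] = vaf(
                X_test, forward(trained, X_test)
            ).aggregate_vaf
            profile = dimension_variance(encode(trained, X))
            block["dimension_variance"][AE_METHOD][str(k)] = {
                "v_dim": profile.v_dim.tolist(),
                "range": profile.range,
            }

        stage = "separability"
        ks = config.separability_k
        sep_seed = _derive_seed(config.seed, 3)
        labels = ds.movement_class
        folds = config.separability_folds

        def sep(Xrep, space, method):
            res = softmax_cv_accuracy(
                Xrep, labels, folds=folds, seed=sep_seed, space=space, method=method
            )
            return {
                "mean_accuracy": res.mean_accuracy,
                "fold_accuracies": res.fold_accuracies.tolist(),
            }

        block["separability"]["original_20d"] = sep(X, "original_20d", "none")
        if ks in config.k_values:
            z_pca = pca_encode(pca_model, X, ks)
            z_ae = encode(ae_models[ks], X)
            latents_2d = {PCA_METHOD: z_pca, AE_METHOD: z_ae}
            block["separability"]["latent_pca"] = sep(z_pca.A, "latent_kd", PCA_METHOD)
            block["separability"]["latent_naen"] = sep(z_ae.A, "latent_kd", AE_METHOD)
            block["separability"]["reconstructed_pca"] = sep(
                pca_decode(pca_model, z_pca), "reconstructed_20d", PCA_METHOD
            )
            block["separability"]["reconstructed_naen"] = sep(
                forward(ae_models[ks], X), "reconstructed_20d", AE_METHOD
            )
        return block, latents_2d, (ds.movement_class, ds.trial_id)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise with context
        logger.error("stage %s failed for participant %s: %s", stage, pid, exc)
        raise PipelineError(f"stage {stage!r} failed for participant {pid}: {exc}") from exc


def _cross_participant_stats(config: ExperimentConfig, participants: dict) -> dict:
    """The four-contrast post-hoc family plus the omnibus tests, all documented
    in the report itself."""
    pids = sorted(participants)
    ks = [str(k) for k in config.k_values]

    def collect(path_fn):
        return np.array([path_fn(participants[p]) for p in pids], dtype=float)

    stats_block = {"alpha": config.alpha, "family": {}}
    adjusted = bonferroni_adjust(config.alpha, 4)
    stats_block["bonferroni_m"] = 4
    stats_block["adjusted_alpha"] = adjusted

    # omnibus: method effect on VAF, paired over participant x k
    ae_vaf = np.array(
        [participants[p]["vaf_test"][AE_METHOD][k] for p in pids for k in ks]
    )
    pca_vaf = np.array(
        [participants[p]["vaf_test"][PCA_METHOD][k] for p in pids for k in ks]
    )
    stats_block["vaf_method_effect"] = _safe_wilcoxon(ae_vaf, pca_vaf, config.alpha)

    # omnibus: latent-size effect on VAF per method (Friedman over k)
    for method in (AE_METHOD, PCA_METHOD):
        scores = np.array(
            [[participants[p]["vaf_test"][method][k] for k in ks] for p in pids]
        )
        if len(pids) >= 2 and len(ks) >= 2:
            stats_block[f"vaf_k_effect_{method.lower()}"] = friedman_test(
                scores, alpha=config.alpha
            ).to_dict()

    family = {}
    # 1: VAF at the smallest k, AE vs PCA across participants
    k0 = ks[0]
    family["vaf_at_smallest_k"] = _safe_wilcoxon(
        collect(lambda b: b["vaf_test"][AE_METHOD][k0]),
        collect(lambda b: b["vaf_test"][PCA_METHOD][k0]),
        adjusted,
    )
    # 2: range of dimension variance, AE vs PCA, pooled over participant x k
    ae_rng = np.array(
        [participants[p]["dimension_variance"][AE_METHOD][k]["range"] for p in pids for k in ks]
    )
    pca_rng = np.array(
        [participants[p]["dimension_variance"][PCA_METHOD][k]["range"] for p in pids for k in ks]
    )
    family["dimension_variance_range"] = _safe_wilcoxon(ae_rng, pca_rng, adjusted)
    # 3 & 4: separability, latent vs reconstructed, per method
    for name, lat_key, rec_key in (
        ("separability_naen_latent_vs_reconstructed", "latent_naen", "reconstructed_naen"),
        ("separability_pca_latent_vs_reconstructed", "latent_pca", "reconstructed_pca"),
    ):
        has = all(lat_key in participants[p]["separability"] for p in pids)
        if has:
            family[name] = _safe_wilcoxon(
                collect(lambda b: b["separability"][rec_key]["mean_accuracy"]),
                collect(lambda b: b["separability"][lat_key]["mean_accuracy"]),
                adjusted,
            )
    stats_block["family"] = family
    return stats_block


def _safe_wilcoxon(x, y, level):
    try:
        out = wilcoxon_signed_rank(x, y, alpha=level)
        d = out.to_dict()
        d["adjusted_alpha"] = level
        d["decision"] = "reject" if out.p_value < level else "fail_to_reject"
        return d
    except Exception as exc:  # degenerate contrast (too few nonzero diffs, etc.)
        return {"test_name": "wilcoxon_signed_rank", "error": str(exc)}


def run_experiment(config: ExperimentConfig, out_dir=None) -> ComparisonReport:
    """Run the full comparison and return (optionally also write) the report."""
    config.validate()
    participants = {}
    sources = (
        [(f"P{i + 1:02d}", ("file", p)) for i, p in enumerate(config.recording_paths)]
        if config.recording_paths
        else [
            (f"SYN{i + 1:02d}", ("seed", s)) for i, s in enumerate(config.seeds())
        ]
    )
    scatter_blocks = {}
    for pid, (kind, source) in sources:
        logger.info("participant %s: loading (%s=%s)", pid, kind, source)
        if kind == "file":
            rec = read_recording(source)
        else:
            rec = generate_dataset(replace(config.synthetic_spec, seed=source))
        block, latents, label_arrays = _analyze_participant(config, pid, rec)
        participants[pid] = block
        if latents:
            scatter_blocks[pid] = (latents, label_arrays)

    payload = {
        "provenance": {
            "package_version": __version__,
            "config": _config_dict(config),
            "participant_sources": {
                pid: {"kind": kind, "source": str(src)} for pid, (kind, src) in sources
            },
            "config_sha256": hashlib.sha256(
                json.dumps(_config_dict(config), sort_keys=True).encode()
            ).hexdigest(),
        },
        "participants": participants,
        "statistics": _cross_participant_stats(config, participants),
    }
    report = ComparisonReport(payload=payload)

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        report.to_json(os.path.join(out_dir, "report.json"))
        report.vaf_table().to_csv(os.path.join(out_dir, "vaf_long.csv"), index=False)
        for pid, (latents, (classes, trials)) in scatter_blocks.items():
            for method, Z in latents.items():
                export_latent_scatter(
                    Z,
                    classes,
                    trials,
                    os.path.join(out_dir, f"latent2d_{pid}_{method.lower()}.csv"),
                )
    return report
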