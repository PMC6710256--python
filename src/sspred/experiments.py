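"""End-to-end desk-scale experiments used by the acceptance checks: the
profile-versus-single-sequence benchmark that reproduces the published
ordering (constant baselines < sequence-only window FFNN < profile-based
CBRCNN) on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import clip, onehot_encode, weighted_profile
from .metrics import q_accuracy
from .model import ModelConfig, count_parameters
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .training import (
    TrainingConfig,
    baseline_predict,
    fit_baseline,
    indices_to_ss,
    ss_to_indices,
    train,
)
from .model import predict_probs


@dataclass
class BenchmarkResult:
    """Held-out 3-state accuracies (percent) of the compared predictors."""

    q3_majority: float
    q3_per_residue_majority: float
    q3_onehot_ffnn: float
    q3_profile_cbrcnn: float
    n_train: int
    n_test: int
    ffnn_parameters: int
    cbrcnn_parameters: int


def small_ffnn_config() -> ModelConfig:
    """Sequence-only window FFNN baseline (20 one-hot inputs, 15-residue window)."""
    return ModelConfig(
        architecture="ffnn", n_inputs=20, n_classes=3, window=7, hidden=(20,)
    )


def small_cbrcnn_config() -> ModelConfig:
    """A small CBRCNN for desk-scale training on 22-wide profiles."""
    return ModelConfig(
        architecture="cbrcnn", n_inputs=22, n_classes=3,
        nf=10, nb=10, nhf=14, nhb=14, nhy=20, cofb=3, cseg=5, cwin=7,
    )


def profile_benchmark(
    cfg: SyntheticConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    ffnn_epochs: int = 25,
    cbrcnn_epochs: int = 80,
    data: SyntheticDataset | None = None,
) -> BenchmarkResult:
    """Train the baselines, a one-hot FFNN and a profile CBRCNN on one
    synthetic dataset and score them on a held-out split.

    The CBRCNN reads clipped entropy-weighted profiles of pseudo-source A;
    the FFNN reads the bare one-hot sequence; the constant baselines are
    fitted on the training split's class statistics.
    """
    if data is None:
        if cfg is None:
            cfg = SyntheticConfig(seed=seed)
        data = generate_dataset(cfg)
    n = len(data.records)
    n_test = max(1, int(round(n * test_fraction)))
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train_idx = [i for i in range(n) if i not in test_idx]
    test_ids = sorted(test_idx)

    records = data.records
    obs3 = {i: None for i in range(n)}
    labels = {}
    for i, rec in enumerate(records):
        from .alphabet import map_8_to_3

        ss3 = map_8_to_3(rec.ss8)
        obs3[i] = ss3
        labels[i] = ss_to_indices(ss3, "ss3")

    # baselines
    ref = fit_baseline([records[i] for i in train_idx])
    test_records = [records[i] for i in test_ids]
    test_obs = [obs3[i] for i in test_ids]
    q3_glob, _ = q_accuracy(
        baseline_predict(test_records, "global_majority", ref), test_obs
    )
    q3_aa, _ = q_accuracy(
        baseline_predict(test_records, "per_residue_majority", ref), test_obs
    )

    # one-hot FFNN
    ffnn_cfg = small_ffnn_config()
    onehots = {i: onehot_encode(records[i]).rows for i in range(n)}
    ffnn_data = [(onehots[i], labels[i]) for i in train_idx]
    tc = TrainingConfig(
        initial_learning_rate=0.2, max_epochs=ffnn_epochs, seed=seed + 2
    )
    ffnn_params, _ = train(ffnn_cfg, tc, ffnn_data)
    pred_ffnn = [
        indices_to_ss(np.argmax(predict_probs(ffnn_params, onehots[i], ffnn_cfg), axis=1))
        for i in test_ids
    ]
    q3_ffnn, _ = q_accuracy(pred_ffnn, test_obs)

    # profile CBRCNN on clipped weighted profiles of source A
    cbr_cfg = small_cbrcnn_config()
    profiles = {
        i: clip(weighted_profile(data.alignments_a[i]), records[i]).rows
        for i in range(n)
    }
    cbr_data = [(profiles[i], labels[i]) for i in train_idx]
    tc = TrainingConfig(
        initial_learning_rate=0.03, max_epochs=cbrcnn_epochs, seed=seed + 3
    )
    cbr_params, _ = train(cbr_cfg, tc, cbr_data)
    pred_cbr = [
        indices_to_ss(np.argmax(predict_probs(cbr_params, profiles[i], cbr_cfg), axis=1))
        for i in test_ids
    ]
    q3_cbr, _ = q_accuracy(pred_cbr, test_obs)

    return BenchmarkResult(
        q3_majority=q3_glob,
        q3_per_residue_majority=q3_aa,
        q3_onehot_ffnn=q3_ffnn,
        q3_profile_cbrcnn=q3_cbr,
        n_train=len(train_idx),
        n_test=n_test,
        ffnn_parameters=count_parameters(ffnn_cfg),
        cbrcnn_parameters=count_parameters(cbr_cfg),
    )
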