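"""Optimization and ensembling: SGD with momentum and an adaptive
learning-rate schedule, incremental FFNN deepening, cross-validation folds,
softmax-averaged ensembles, and the 3-state -> 8-state prediction cascade.

Training minimizes the summed per-residue cross-entropy of the model's
softmax outputs (both stages of a CBRCNN; the stage-2 output is the
prediction) by stochastic gradient descent with momentum 0.9.  Gradients are averaged over the residues of a minibatch of
~10 proteins; the protein order is reshuffled at the end of every epoch;
and the learning rate is halved whenever the training cross-entropy has not
improved on its best value for ``patience_epochs`` epochs (default 100).
Everything is reproducible bit-for-bit from the training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .alphabet import SS3, SS3_INDEX, SS8, SS8_INDEX, map_8_to_3
from .encoding import EncodedSequence, augment_with_ss3
from .io_formats import ProteinRecord
from .model import (
    ModelConfig,
    ModelParams,
    init_params,
    loss_and_grads,
    predict_probs,
)


class TrainingDiverged(RuntimeError):
    """Training produced a non-finite loss; no parameters are returned."""


@dataclass
class TrainingConfig:
    initial_learning_rate: float = 0.01
    momentum: float = 0.9
    patience_epochs: int = 100
    minibatch_proteins: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.patience_epochs < 1 or self.minibatch_proteins < 1:
            raise ValueError("patience and minibatch size must be >= 1")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch training cross-entropy (per residue) and learning rate."""

    losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def epochs_run(self) -> int:
        return len(self.losses)


def ss_to_indices(ss: str, level: str = "ss3", dialect: str = "default") -> np.ndarray:
    """Integer class labels for a secondary-structure string."""
    if level == "ss3":
        return np.array([SS3_INDEX[c] for c in ss], dtype=int)
    if level == "ss8":
        return np.array([SS8_INDEX[c] for c in ss], dtype=int)
    raise ValueError(f"level must be 'ss3' or 'ss8', got {level!r}")


def indices_to_ss(y: np.ndarray, level: str = "ss3") -> str:
    symbols = SS3 if level == "ss3" else SS8
    return "".join(symbols[i] for i in y)


def train(
    config: ModelConfig,
    tc: TrainingConfig,
    data: Sequence[tuple[np.ndarray, np.ndarray]],
    init: ModelParams | None = None,
) -> tuple[ModelParams, TrainingHistory]:
    """Train a model on ``[(X, y), ...]`` pairs (per-protein input matrices
    and integer labels).

    If ``init`` is given, training continues from it (the refinement
    strategy: a model trained on one alignment source can be refined on
    another).  Blocks named in ``init.frozen`` are not updated.  Returns the
    trained parameters and the per-epoch history.
    """
    if not data:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tc.seed)
    params = init.copy() if init is not None else init_params(config, rng)
    params.validate_against(config)
    velocity = {k: np.zeros_like(v) for k, v in params.blocks.items()}
    lr = tc.initial_learning_rate
    best = np.inf
    since_best = 0
    history = TrainingHistory(seed=tc.seed)
    order = np.arange(len(data))
    total_residues = sum(len(y) for _, y in data)

    for _epoch in range(tc.max_epochs):
        epoch_loss = 0.0
        for start in range(0, len(order), tc.minibatch_proteins):
            batch = order[start : start + tc.minibatch_proteins]
            n_res = sum(len(data[i][1]) for i in batch)
            acc: dict[str, np.ndarray] = {}
            for i in batch:
                X, y = data[i]
                loss, grads = loss_and_grads(params, config, X, y, scale=1.0 / n_res)
                epoch_loss += loss
                for k, g in grads.items():
                    if k in acc:
                        acc[k] += g
                    else:
                        acc[k] = g
            for k, g in acc.items():
                if k in params.frozen:
                    continue
                velocity[k] = tc.momentum * velocity[k] - lr * g
                params.blocks[k] += velocity[k]
        per_residue = epoch_loss / total_residues
        if not np.isfinite(per_residue):
            raise TrainingDiverged(
                f"non-finite training loss at epoch {len(history.losses) + 1} "
                f"(lr={lr:g}); try a smaller learning rate"
            )
        history.losses.append(per_residue)
        history.learning_rates.append(lr)
        if per_residue < best - 1e-12:
            best = per_residue
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience_epochs:
                lr /= 2.0
                since_best = 0
        rng.shuffle(order)
    return params, history


# ---------------------------------------------------------------------------
# Incremental FFNN deepening
# ---------------------------------------------------------------------------

def incremental_deepen(
    params: ModelParams,
    config: ModelConfig,
    new_hidden_size: int,
    rng: np.random.Generator,
) -> tuple[ModelParams, ModelConfig]:
    """Replace an FFNN's softmax layer with a fresh hidden + softmax block.

    The existing hidden layers are kept bit-identical and marked frozen, so
    a subsequent :func:`train` call trains only the new top block; lift the
    freeze with :func:`unfreeze` to refine end to end.
    """
    if config.architecture != "ffnn":
        raise ValueError("incremental deepening applies to FFNN models only")
    new_config = replace(config, hidden=config.hidden + (new_hidden_size,))
    h_prev = config.hidden[-1]
    i_new = len(config.hidden)
    blocks = {
        k: v.copy() for k, v in params.blocks.items() if not k.startswith("ffnn.out")
    }
    s = 1.0 / np.sqrt(h_prev)
    blocks[f"ffnn.layer{i_new}.W"] = rng.uniform(-s, s, (new_hidden_size, h_prev))
    blocks[f"ffnn.layer{i_new}.b"] = np.zeros(new_hidden_size)
    s = 1.0 / np.sqrt(new_hidden_size)
    blocks["ffnn.out.W"] = rng.uniform(-s, s, (config.n_classes, new_hidden_size))
    blocks["ffnn.out.b"] = np.zeros(config.n_classes)
    frozen = frozenset(
        k for k in blocks if k.startswith("ffnn.layer") and not k.startswith(f"ffnn.layer{i_new}.")
    )
    return ModelParams(blocks=blocks, frozen=frozen), new_config


def unfreeze(params: ModelParams) -> ModelParams:
    return ModelParams(blocks=params.blocks, frozen=frozenset())


# ---------------------------------------------------------------------------
# Folds and ensembles
# ---------------------------------------------------------------------------

def make_cv_folds(records: Sequence, k: int = 5, seed: int = 0) -> list[list]:
    """Random partition into k folds with sizes differing by at most one."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [[records[i] for i in chunk] for chunk in np.array_split(order, k)]


def ensemble_average(outputs: Sequence[np.ndarray]) -> np.ndarray:
    """Componentwise mean of member softmax outputs (rows stay normalized)."""
    if not outputs:
        raise ValueError("empty ensemble")
    stack = np.stack([np.asarray(o, float) for o in outputs])
    if any(o.shape != stack[0].shape for o in stack):
        raise ValueError("ensemble members have differing output shapes")
    return stack.mean(axis=0)


@dataclass
class EnsembleMember:
    """A trained model plus the input scheme it expects.

    ``source`` names the profile the member reads: ``"a"`` or ``"b"`` for the
    two alignment sources, ``"concat"`` for their 44-wide concatenation.
    """

    params: ModelParams
    config: ModelConfig
    source: str

    def __post_init__(self) -> None:
        if self.source not in ("a", "b", "concat"):
            raise ValueError(f"unknown input source {self.source!r}")


@dataclass
class EnsembleSpec:
    members: list[EnsembleMember]

    def __post_init__(self) -> None:
        classes = {m.config.n_classes for m in self.members}
        if len(classes) != 1:
            raise ValueError("ensemble members must share n_classes")

    @property
    def n_classes(self) -> int:
        return self.members[0].config.n_classes

    def sources(self) -> set[str]:
        return {m.source for m in self.members}


@dataclass
class CascadeResult:
    """Per-residue probabilities and argmax strings of the full cascade."""

    p3: np.ndarray
    ss3: str
    p8: np.ndarray | None = None
    ss8: str | None = None
    member_outputs_3: list[np.ndarray] = field(default_factory=list)
    member_outputs_8: list[np.ndarray] = field(default_factory=list)


def _member_input(member: EnsembleMember, profiles: dict[str, EncodedSequence]):
    try:
        return profiles[member.source]
    except KeyError:
        raise ValueError(
            f"no profile provided for input source {member.source!r} "
            f"(have: {sorted(profiles)})"
        ) from None


def predict_cascade(
    record: ProteinRecord,
    profiles: dict[str, EncodedSequence],
    ens3: EnsembleSpec,
    ens8: EnsembleSpec | None = None,
) -> CascadeResult:
    """Run the 3-state ensemble and, optionally, the 8-state cascade.

    Every 3-state member reads its own profile scheme; the ensemble output
    is the componentwise mean.  Each 8-state member reads its profile
    augmented with the 3-state output of the *matching source group* (the
    concatenated member receives the average of all 3-state members).
    Class strings are argmax with ties broken toward the lowest class index.
    """
    if ens3.n_classes != 3:
        raise ValueError("ens3 must contain 3-class members")
    out3 = [
        predict_probs(m.params, _member_input(m, profiles), m.config)
        for m in ens3.members
    ]
    p3 = ensemble_average(out3)
    group3: dict[str, np.ndarray] = {}
    for src in ens3.sources():
        group3[src] = ensemble_average(
            [o for o, m in zip(out3, ens3.members) if m.source == src]
        )
    ss3 = indices_to_ss(np.argmax(p3, axis=1), "ss3")
    result = CascadeResult(p3=p3, ss3=ss3, member_outputs_3=out3)
    if ens8 is None:
        return result
    if ens8.n_classes != 8:
        raise ValueError("ens8 must contain 8-class members")
    out8 = []
    for m in ens8.members:
        base = _member_input(m, profiles)
        aug_probs = p3 if m.source == "concat" else group3.get(m.source, p3)
        enc = augment_with_ss3(base, aug_probs)
        out8.append(predict_probs(m.params, enc, m.config))
    p8 = ensemble_average(out8)
    result.p8 = p8
    result.ss8 = indices_to_ss(np.argmax(p8, axis=1), "ss8")
    result.member_outputs_8 = out8
    return result


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineReference:
    """Class statistics of a training split, for the constant baselines."""

    global_majority: str
    per_residue_majority: dict[str, str]


def fit_baseline(records: Sequence[ProteinRecord], dialect: str = "default") -> BaselineReference:
    """Most frequent 3-state class overall and per residue type."""
    from collections import Counter

    overall: Counter[str] = Counter()
    per_aa: dict[str, Counter] = {}
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id!r} carries no labels")
        ss3 = map_8_to_3(rec.ss8, dialect)
        overall.update(ss3)
        for aa, cls in zip(rec.sequence, ss3):
            per_aa.setdefault(aa, Counter()).update(cls)
    # ties break toward the lowest class index (H before E before C)
    def argmax(counter: Counter) -> str:
        return max(SS3, key=lambda c: (counter.get(c, 0), -SS3_INDEX[c]))

    return BaselineReference(
        global_majority=argmax(overall),
        per_residue_majority={aa: argmax(c) for aa, c in per_aa.items()},
    )


def baseline_predict(
    records: Sequence[ProteinRecord],
    mode: str,
    reference: BaselineReference,
) -> list[str]:
    """Constant-class baselines: the training majority class everywhere, or
    each residue type's majority class."""
    if mode == "global_majority":
        return [reference.global_majority * len(r) for r in records]
    if mode == "per_residue_majority":
        fallback = reference.global_majority
        return [
            "".join(reference.per_residue_majority.get(aa, fallback) for aa in r.sequence)
            for r in records
        ]
    raise ValueError(f"unknown baseline mode {mode!r}")
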