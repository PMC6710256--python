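"""Predictive architectures: window-based feed-forward baselines and the
two-stage cascaded bidirectional-recurrent + convolutional network (CBRCNN).

The CBRCNN processes a protein of length L as follows, per stage:

* a forward memory chain of size NF is updated left-to-right by a small
  transition network reading ``[previous memory, current input]`` through two
  tanh hidden layers of size NHF; a backward chain (NB, NHB) with independent
  weights runs right-to-left; both start from zero memories;
* a 1-D convolutional layer with kernel ``2*CoFB + 1`` reads a window of the
  concatenated ``[forward, backward]`` memories into NHY tanh units;
* a kernel-1 convolution maps NHY units to the class softmax.

The second stage repeats the topology at (ceil) half sizes.  Its input at
position n is the first stage's class distribution averaged over Cseg
contiguous segments of Cwin positions tiled around n (the default 15
segments of 21 steps summarize 315 positions per prediction); positions
beyond the termini count as zero rows.  The stage-2 output is the model's
prediction.  Training scores both stages' softmax outputs against the
labels and backpropagates end to end (see :func:`loss_and_grads`).

All forward/backward passes are plain NumPy; gradients are exercised against
finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .encoding import EncodedSequence


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of an FFNN or CBRCNN model.

    FFNN fields: ``window`` (half-width l; the input window spans 2l+1
    residues) and ``hidden`` (sizes of the fully connected tanh layers).

    CBRCNN fields: memory sizes ``nf``/``nb``, transition hidden sizes
    ``nhf``/``nhb``, pre-softmax size ``nhy``, conv half-width ``cofb``
    (kernel = 2*cofb+1), segment tiling ``cseg`` x ``cwin``.  Stage-2 sizes
    are ceil(stage-1 / 2).  ``cell_hidden_layers`` selects one or two hidden
    layers inside the transition network; ``conv_sees_input`` optionally
    feeds the raw input window to the conv layer as well (off by default:
    the conv layers read only the chain memories).
    """

    architecture: str
    n_inputs: int
    n_classes: int
    # ffnn
    window: int = 7
    hidden: tuple[int, ...] = (50,)
    # cbrcnn
    nf: int = 25
    nb: int = 30
    nhf: int = 40
    nhb: int = 40
    nhy: int = 50
    cofb: int = 3
    cseg: int = 15
    cwin: int = 21
    cell_hidden_layers: int = 2
    conv_sees_input: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ("ffnn", "cbrcnn"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "ffnn":
            if self.window < 0:
                raise ValueError("window half-width must be >= 0")
            if not self.hidden:
                raise ValueError("ffnn needs at least one hidden layer")
        else:
            if self.cofb < 0:
                raise ValueError("cofb must be >= 0")
            if self.cseg < 1 or self.cwin < 1:
                raise ValueError("cseg and cwin must be >= 1")
            if self.cell_hidden_layers not in (1, 2):
                raise ValueError("cell_hidden_layers must be 1 or 2")
        if self.n_classes < 2 or self.n_inputs < 1:
            raise ValueError("need n_inputs >= 1 and n_classes >= 2")

    @property
    def kernel_size(self) -> int:
        return 2 * self.cofb + 1

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["hidden"] = list(self.hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["hidden"] = tuple(d.get("hidden", (50,)))
        return cls(**d)


@dataclass
class ModelParams:
    """Named parameter blocks plus the set of blocks frozen during training."""

    blocks: dict[str, np.ndarray]
    frozen: frozenset[str] = field(default_factory=frozenset)

    def n_parameters(self) -> int:
        return sum(b.size for b in self.blocks.values())

    def copy(self) -> "ModelParams":
        return ModelParams(
            blocks={k: v.copy() for k, v in self.blocks.items()},
            frozen=self.frozen,
        )

    def validate_against(self, config: "ModelConfig") -> None:
        expected = dict(param_shapes(config))
        got = {k: v.shape for k, v in self.blocks.items()}
        if expected != got:
            raise ValueError(
                f"parameter blocks do not match config: expected {expected}, got {got}"
            )


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

def _half(x: int) -> int:
    return math.ceil(x / 2)


@dataclass(frozen=True)
class _StageDims:
    d_in: int
    nf: int
    nb: int
    nhf: int
    nhb: int
    nhy: int
    n_classes: int
    kernel: int
    conv_sees_input: bool
    cell_hidden_layers: int

    @property
    def conv_width(self) -> int:
        m = self.nf + self.nb + (self.d_in if self.conv_sees_input else 0)
        return self.kernel * m


def stage_dims(config: ModelConfig, stage: int) -> _StageDims:
    """Layer sizes of stage 1 or 2 of a CBRCNN config."""
    assert config.architecture == "cbrcnn" and stage in (1, 2)
    if stage == 1:
        return _StageDims(
            d_in=config.n_inputs,
            nf=config.nf, nb=config.nb, nhf=config.nhf, nhb=config.nhb,
            nhy=config.nhy, n_classes=config.n_classes,
            kernel=config.kernel_size, conv_sees_input=config.conv_sees_input,
            cell_hidden_layers=config.cell_hidden_layers,
        )
    return _StageDims(
        d_in=config.cseg * config.n_classes,
        nf=_half(config.nf), nb=_half(config.nb),
        nhf=_half(config.nhf), nhb=_half(config.nhb),
        nhy=_half(config.nhy), n_classes=config.n_classes,
        kernel=config.kernel_size, conv_sees_input=config.conv_sees_input,
        cell_hidden_layers=config.cell_hidden_layers,
    )


def _stage_shapes(prefix: str, dims: _StageDims) -> Iterator[tuple[str, tuple]]:
    for tag, nm, nh in (("f", dims.nf, dims.nhf), ("b", dims.nb, dims.nhb)):
        yield f"{prefix}.{tag}.W1", (nh, nm + dims.d_in)
        yield f"{prefix}.{tag}.b1", (nh,)
        if dims.cell_hidden_layers == 2:
            yield f"{prefix}.{tag}.W2", (nh, nh)
            yield f"{prefix}.{tag}.b2", (nh,)
        yield f"{prefix}.{tag}.W3", (nm, nh)
        yield f"{prefix}.{tag}.b3", (nm,)
    yield f"{prefix}.conv1.W", (dims.nhy, dims.conv_width)
    yield f"{prefix}.conv1.b", (dims.nhy,)
    yield f"{prefix}.out.W", (dims.n_classes, dims.nhy)
    yield f"{prefix}.out.b", (dims.n_classes,)


def param_shapes(config: ModelConfig) -> list[tuple[str, tuple]]:
    """Ordered (name, shape) of every trainable block implied by a config."""
    shapes: list[tuple[str, tuple]] = []
    if config.architecture == "ffnn":
        d = (2 * config.window + 1) * config.n_inputs
        prev = d
        for i, h in enumerate(config.hidden):
            shapes.append((f"ffnn.layer{i}.W", (h, prev)))
            shapes.append((f"ffnn.layer{i}.b", (h,)))
            prev = h
        shapes.append(("ffnn.out.W", (config.n_classes, prev)))
        shapes.append(("ffnn.out.b", (config.n_classes,)))
    else:
        for stage in (1, 2):
            shapes.extend(_stage_shapes(f"s{stage}", stage_dims(config, stage)))
    return shapes


def count_parameters(config: ModelConfig) -> int:
    """Exact number of trainable scalars (weights and biases) of a config."""
    return sum(int(np.prod(shape)) for _, shape in param_shapes(config))


def init_params(config: ModelConfig, rng: np.random.Generator) -> ModelParams:
    """Symmetric uniform initialization scaled by fan-in; biases start at 0."""
    blocks = {}
    for name, shape in param_shapes(config):
        if name.endswith(".b") or name.endswith("b1") or name.endswith("b2") or name.endswith("b3"):
            blocks[name] = np.zeros(shape)
        else:
            fan_in = shape[1] if len(shape) == 2 else shape[0]
            s = 1.0 / math.sqrt(fan_in)
            blocks[name] = rng.uniform(-s, s, size=shape)
    return ModelParams(blocks=blocks)


# ---------------------------------------------------------------------------
# Shared pieces
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _window_matrix(rows: np.ndarray, half: int) -> np.ndarray:
    """L x (2*half+1)*D matrix of zero-padded symmetric windows."""
    L, D = rows.shape
    if half == 0:
        return rows
    padded = np.vstack([np.zeros((half, D)), rows, np.zeros((half, D))])
    return np.hstack([padded[i : i + L] for i in range(2 * half + 1)])


def make_window_input(enc: EncodedSequence, n: int, l: int) -> np.ndarray:
    """Input window I(n) = v_{n-l} .. v_{n+l} at 1-based position n.

    Out-of-range rows are zero vectors, so the window always has width
    (2l+1)*D.
    """
    if l < 0:
        raise ValueError("window half-width must be >= 0")
    L = len(enc)
    if not 1 <= n <= L:
        raise ValueError(f"position {n} out of range 1..{L}")
    return _window_matrix(enc.rows, l)[n - 1]


def _as_rows(enc) -> np.ndarray:
    return enc.rows if isinstance(enc, EncodedSequence) else np.asarray(enc, float)


# ---------------------------------------------------------------------------
# FFNN
# ---------------------------------------------------------------------------

def _ffnn_forward(params: ModelParams, X: np.ndarray, config: ModelConfig):
    if X.shape[1] != config.n_inputs:
        raise ValueError(
            f"input width {X.shape[1]} != configured n_inputs {config.n_inputs}"
        )
    W = params.blocks
    win = _window_matrix(X, config.window)
    acts = [win]
    h = win
    for i in range(len(config.hidden)):
        h = np.tanh(h @ W[f"ffnn.layer{i}.W"].T + W[f"ffnn.layer{i}.b"])
        acts.append(h)
    logits = h @ W["ffnn.out.W"].T + W["ffnn.out.b"]
    return softmax(logits), acts


def forward_ffnn(params: ModelParams, enc, config: ModelConfig) -> np.ndarray:
    """Per-residue class distributions of a window-based FFNN (L x C)."""
    probs, _ = _ffnn_forward(params, _as_rows(enc), config)
    return probs


def _ffnn_backward(params, config, acts, dlogits):
    W = params.blocks
    grads = {}
    grads["ffnn.out.W"] = dlogits.T @ acts[-1]
    grads["ffnn.out.b"] = dlogits.sum(axis=0)
    dh = dlogits @ W["ffnn.out.W"]
    for i in reversed(range(len(config.hidden))):
        dpre = dh * (1.0 - acts[i + 1] ** 2)
        grads[f"ffnn.layer{i}.W"] = dpre.T @ acts[i]
        grads[f"ffnn.layer{i}.b"] = dpre.sum(axis=0)
        dh = dpre @ W[f"ffnn.layer{i}.W"]
    return grads


# ---------------------------------------------------------------------------
# Segment averaging (stage 1 -> stage 2 interface)
# ---------------------------------------------------------------------------

def _block_offsets(cseg: int, cwin: int) -> list[int]:
    """Start offset (relative to n) of each of the Cseg blocks.

    Blocks are contiguous and tiled around n with the middle block centered
    at n; for even Cseg the extra block sits to the right.
    """
    mid = (cseg - 1) // 2
    return [(j - mid) * cwin - (cwin - 1) // 2 for j in range(cseg)]


def segment_features(probs: np.ndarray, cseg: int, cwin: int) -> np.ndarray:
    """Stage-2 input: per position, Cseg block means of stage-1 output.

    Positions beyond the termini count as zero rows, i.e. every block mean
    divides by Cwin regardless of truncation.  Returns L x (Cseg * C).
    """
    L, C = probs.shape
    cum = np.vstack([np.zeros(C), np.cumsum(probs, axis=0)])  # cum[i] = sum rows < i
    n_idx = np.arange(L)
    feats = np.empty((L, cseg * C))
    for j, off in enumerate(_block_offsets(cseg, cwin)):
        start = np.clip(n_idx + off, 0, L)
        stop = np.clip(n_idx + off + cwin, 0, L)
        feats[:, j * C : (j + 1) * C] = (cum[stop] - cum[start]) / cwin
    return feats


def segment_average(stage1_out: np.ndarray, n: int, cseg: int, cwin: int) -> np.ndarray:
    """Segment-averaged stage-2 input vector at 1-based position n."""
    L = stage1_out.shape[0]
    if not 1 <= n <= L:
        raise ValueError(f"position {n} out of range 1..{L}")
    return segment_features(np.asarray(stage1_out, float), cseg, cwin)[n - 1]


def _segment_features_vjp(dfeats: np.ndarray, cseg: int, cwin: int, C: int) -> np.ndarray:
    """Adjoint of :func:`segment_features`: gradient w.r.t. stage-1 output."""
    L = dfeats.shape[0]
    dprobs = np.zeros((L, C))
    for j, off in enumerate(_block_offsets(cseg, cwin)):
        block = dfeats[:, j * C : (j + 1) * C] / cwin
        for o in range(cwin):
            t = off + o  # dprobs[n + t] += block[n]
            lo, hi = max(0, -t), min(L, L - t)
            if lo < hi:
                dprobs[lo + t : hi + t] += block[lo:hi]
    return dprobs


# ---------------------------------------------------------------------------
# CBRCNN
# ---------------------------------------------------------------------------

def _chain_forward(W, prefix, tag, X, nm, two_layer):
    """Run one memory chain over the sequence; tag 'f' is left-to-right."""
    L = X.shape[0]
    W1, b1 = W[f"{prefix}.{tag}.W1"], W[f"{prefix}.{tag}.b1"]
    W3, b3 = W[f"{prefix}.{tag}.W3"], W[f"{prefix}.{tag}.b3"]
    W2 = W.get(f"{prefix}.{tag}.W2")
    b2 = W.get(f"{prefix}.{tag}.b2")
    order = range(L) if tag == "f" else range(L - 1, -1, -1)
    A = np.empty((L, nm + X.shape[1]))
    Z1 = np.empty((L, W1.shape[0]))
    Z2 = np.empty_like(Z1) if two_layer else None
    M = np.empty((L, nm))
    mem = np.zeros(nm)
    for n in order:
        a = np.concatenate([mem, X[n]])
        z1 = np.tanh(W1 @ a + b1)
        z = z1
        if two_layer:
            z = np.tanh(W2 @ z1 + b2)
            Z2[n] = z
        mem = np.tanh(W3 @ z + b3)
        A[n], Z1[n], M[n] = a, z1, mem
    return {"A": A, "Z1": Z1, "Z2": Z2, "M": M}


def _chain_backward(W, prefix, tag, cache, dM, nm, two_layer):
    L = dM.shape[0]
    W1 = W[f"{prefix}.{tag}.W1"]
    W3 = W[f"{prefix}.{tag}.W3"]
    W2 = W.get(f"{prefix}.{tag}.W2")
    A, Z1, Z2, M = cache["A"], cache["Z1"], cache["Z2"], cache["M"]
    g = {
        f"{prefix}.{tag}.W1": np.zeros_like(W1),
        f"{prefix}.{tag}.b1": np.zeros(W1.shape[0]),
        f"{prefix}.{tag}.W3": np.zeros_like(W3),
        f"{prefix}.{tag}.b3": np.zeros(nm),
    }
    if two_layer:
        g[f"{prefix}.{tag}.W2"] = np.zeros_like(W2)
        g[f"{prefix}.{tag}.b2"] = np.zeros(W2.shape[0])
    dX = np.zeros((L, A.shape[1] - nm))
    # gradient flows against the chain direction
    order = range(L - 1, -1, -1) if tag == "f" else range(L)
    carry = np.zeros(nm)
    for n in order:
        dm = dM[n] + carry
        dpre3 = dm * (1.0 - M[n] ** 2)
        z_last = Z2[n] if two_layer else Z1[n]
        g[f"{prefix}.{tag}.W3"] += np.outer(dpre3, z_last)
        g[f"{prefix}.{tag}.b3"] += dpre3
        dz = W3.T @ dpre3
        if two_layer:
            dpre2 = dz * (1.0 - Z2[n] ** 2)
            g[f"{prefix}.{tag}.W2"] += np.outer(dpre2, Z1[n])
            g[f"{prefix}.{tag}.b2"] += dpre2
            dz = W2.T @ dpre2
        dpre1 = dz * (1.0 - Z1[n] ** 2)
        g[f"{prefix}.{tag}.W1"] += np.outer(dpre1, A[n])
        g[f"{prefix}.{tag}.b1"] += dpre1
        da = W1.T @ dpre1
        carry = da[:nm]
        dX[n] = da[nm:]
    return g, dX


def _stage_forward(params: ModelParams, prefix: str, X: np.ndarray, dims: _StageDims):
    W = params.blocks
    two = dims.cell_hidden_layers == 2
    fcache = _chain_forward(W, prefix, "f", X, dims.nf, two)
    bcache = _chain_forward(W, prefix, "b", X, dims.nb, two)
    M = np.hstack([fcache["M"], bcache["M"]])
    if dims.conv_sees_input:
        M = np.hstack([M, X])
    win = _window_matrix(M, (dims.kernel - 1) // 2)
    U = np.tanh(win @ W[f"{prefix}.conv1.W"].T + W[f"{prefix}.conv1.b"])
    logits = U @ W[f"{prefix}.out.W"].T + W[f"{prefix}.out.b"]
    return {
        "X": X, "f": fcache, "b": bcache, "win": win, "U": U,
        "logits": logits, "probs": softmax(logits),
    }


def _stage_backward(params: ModelParams, prefix: str, cache, dims: _StageDims, dlogits):
    W = params.blocks
    two = dims.cell_hidden_layers == 2
    L = dlogits.shape[0]
    U, win, X = cache["U"], cache["win"], cache["X"]
    g = {
        f"{prefix}.out.W": dlogits.T @ U,
        f"{prefix}.out.b": dlogits.sum(axis=0),
    }
    dU = dlogits @ W[f"{prefix}.out.W"]
    dpre = dU * (1.0 - U ** 2)
    g[f"{prefix}.conv1.W"] = dpre.T @ win
    g[f"{prefix}.conv1.b"] = dpre.sum(axis=0)
    dwin = dpre @ W[f"{prefix}.conv1.W"]
    # adjoint of the window construction
    m = dwin.shape[1] // dims.kernel
    half = (dims.kernel - 1) // 2
    dMp = np.zeros((L + 2 * half, m))
    for i in range(dims.kernel):
        dMp[i : i + L] += dwin[:, i * m : (i + 1) * m]
    dM = dMp[half : half + L]
    dX = np.zeros_like(X)
    if dims.conv_sees_input:
        dX += dM[:, dims.nf + dims.nb :]
    gf, dXf = _chain_backward(W, prefix, "f", cache["f"], dM[:, : dims.nf], dims.nf, two)
    gb, dXb = _chain_backward(
        W, prefix, "b", cache["b"], dM[:, dims.nf : dims.nf + dims.nb], dims.nb, two
    )
    g.update(gf)
    g.update(gb)
    dX += dXf + dXb
    return g, dX


def _cbrcnn_forward(params: ModelParams, X: np.ndarray, config: ModelConfig):
    if X.shape[1] != config.n_inputs:
        raise ValueError(
            f"input width {X.shape[1]} != configured n_inputs {config.n_inputs}"
        )
    d1 = stage_dims(config, 1)
    d2 = stage_dims(config, 2)
    c1 = _stage_forward(params, "s1", X, d1)
    X2 = segment_features(c1["probs"], config.cseg, config.cwin)
    c2 = _stage_forward(params, "s2", X2, d2)
    return c1, c2


def forward_cbrcnn(params: ModelParams, enc, config: ModelConfig):
    """Both stage outputs of a CBRCNN; the stage-2 output is the prediction.

    Returns ``(stage1_probs, stage2_probs)``, each L x n_classes with rows
    summing to 1.
    """
    c1, c2 = _cbrcnn_forward(params, _as_rows(enc), config)
    return c1["probs"], c2["probs"]


def _cbrcnn_backward(params, config, c1, c2, dlogits2, dlogits1_direct=None):
    d1 = stage_dims(config, 1)
    d2 = stage_dims(config, 2)
    g2, dX2 = _stage_backward(params, "s2", c2, d2, dlogits2)
    dP1 = _segment_features_vjp(dX2, config.cseg, config.cwin, config.n_classes)
    P1 = c1["probs"]
    # softmax vector-Jacobian product
    dlogits1 = P1 * (dP1 - (dP1 * P1).sum(axis=1, keepdims=True))
    if dlogits1_direct is not None:
        dlogits1 = dlogits1 + dlogits1_direct
    g1, _ = _stage_backward(params, "s1", c1, d1, dlogits1)
    g1.update(g2)
    return g1


# ---------------------------------------------------------------------------
# Unified prediction / loss API
# ---------------------------------------------------------------------------

def predict_probs(params: ModelParams, enc, config: ModelConfig) -> np.ndarray:
    """Final per-residue class distributions of either architecture."""
    if config.architecture == "ffnn":
        return forward_ffnn(params, enc, config)
    return forward_cbrcnn(params, enc, config)[1]


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Summed per-residue cross-entropy against integer class labels."""
    p = probs[np.arange(len(y)), y]
    return float(-np.sum(np.log(np.maximum(p, 1e-300))))


def loss_and_grads(params: ModelParams, config: ModelConfig, X: np.ndarray,
                   y: np.ndarray, scale: float = 1.0):
    """Training loss and parameter gradients for one protein.

    For an FFNN this is the summed per-residue cross-entropy of its softmax
    output.  For a CBRCNN both stages emit class distributions and both are
    scored against the labels: the loss sums the stage-2 and the stage-1
    cross-entropy.  The stage-1 term supervises the first stage directly —
    without it the only gradient reaching stage 1 is the weak one filtered
    through the segment averages, and training stalls near the uniform
    output.  The stage-2 output remains the model's prediction.

    ``scale`` multiplies the gradient (used to average over a minibatch's
    residues); the returned loss is the unscaled per-protein sum.
    """
    Y = np.zeros((len(y), config.n_classes))
    Y[np.arange(len(y)), y] = 1.0
    if config.architecture == "ffnn":
        probs, acts = _ffnn_forward(params, X, config)
        loss = cross_entropy(probs, y)
        grads = _ffnn_backward(params, config, acts, (probs - Y) * scale)
    else:
        c1, c2 = _cbrcnn_forward(params, X, config)
        loss = cross_entropy(c2["probs"], y) + cross_entropy(c1["probs"], y)
        grads = _cbrcnn_backward(
            params, config, c1, c2,
            (c2["probs"] - Y) * scale,
            dlogits1_direct=(c1["probs"] - Y) * scale,
        )
    return loss, grads


def reverse_equivalent_params(params: ModelParams, config: ModelConfig) -> ModelParams:
    """Parameters computing the position-reversed function of ``params``.

    Swaps the forward/backward chain blocks of both stages and flips the
    conv kernels accordingly.  Requires nf == nb, nhf == nhb and odd cseg
    (the segment tiling must be symmetric).  With these, running the result
    on a reversed input reverses the output sequence — the symmetry oracle
    used in the tests.
    """
    if config.nf != config.nb or config.nhf != config.nhb:
        raise ValueError("reversal symmetry needs nf == nb and nhf == nhb")
    if config.cseg % 2 == 0 or config.cwin % 2 == 0:
        raise ValueError("reversal symmetry needs odd cseg and cwin")
    blocks = {}
    for name, arr in params.blocks.items():
        if ".f." in name:
            blocks[name.replace(".f.", ".b.")] = arr.copy()
        elif ".b." in name:
            blocks[name.replace(".b.", ".f.")] = arr.copy()
        else:
            blocks[name] = arr.copy()
    for stage in (1, 2):
        dims = stage_dims(config, stage)
        key = f"s{stage}.conv1.W"
        W = blocks[key]
        m = dims.nf + dims.nb + (dims.d_in if dims.conv_sees_input else 0)
        Wk = W.reshape(W.shape[0], dims.kernel, m)
        Wk = Wk[:, ::-1, :].copy()  # flip window positions
        # swap the forward/backward memory sub-blocks (sizes equal)
        f_part = Wk[:, :, : dims.nf].copy()
        b_part = Wk[:, :, dims.nf : dims.nf + dims.nb].copy()
        Wk[:, :, : dims.nf] = b_part
        Wk[:, :, dims.nf : dims.nf + dims.nb] = f_part
        if dims.conv_sees_input and stage == 2:
            # stage-2 raw input is the segment feature vector, whose blocks
            # mirror under reversal
            rest = Wk[:, :, dims.nf + dims.nb :]
            C = dims.n_classes
            rest = rest.reshape(W.shape[0], dims.kernel, -1, C)[:, :, ::-1, :]
            Wk[:, :, dims.nf + dims.nb :] = rest.reshape(W.shape[0], dims.kernel, -1)
        blocks[key] = Wk.reshape(W.shape)
    # stage-2 cell inputs are segment features, whose Cseg blocks also mirror
    d2 = stage_dims(config, 2)
    C = d2.n_classes
    for tag, nm in (("f", d2.nf), ("b", d2.nb)):
        key = f"s2.{tag}.W1"
        W1 = blocks[key]
        inp = W1[:, nm:].reshape(W1.shape[0], config.cseg, C)[:, ::-1, :]
        W1 = W1.copy()
        W1[:, nm:] = inp.reshape(W1.shape[0], -1)
        blocks[key] = W1
    return ModelParams(blocks=blocks, frozen=params.frozen)
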