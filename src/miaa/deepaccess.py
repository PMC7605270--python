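"""Multitask CNN ensemble for cell-type accessibility prediction.

An ensemble of ten small networks maps one-hot encoded 100-nt sequences to
two sigmoid outputs, the probabilities that the sequence is open in each of
the two cell types (ESC and definitive endoderm). Nine members are
convolutional (one or two conv layers of varying filter width and count,
global max pooling, a dense output); the tenth is purely linear, with no
trainable hidden layer. The linear member provides the baseline against
which saliency *gain* is measured: motifs whose importance increases in the
convolutional members are those whose effect depends on sequence context
rather than additive single-motif content.

Motif extraction uses smoothed gradients of the differential objective
(the DE logit minus the ESC logit): gradients are averaged under Gaussian
input perturbation, multiplied elementwise by the one-hot input (gradients
assign nonzero weight to absent bases otherwise), averaged over ensemble
members, and the highest-scoring 10-nt windows are reported as candidate
differential-accessibility motifs.

The network layer stack is implemented directly on NumPy arrays (forward,
backward and Adam updates), sized for CPU training on tens of thousands of
short sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score

from .design import DesignedSequence

__all__ = [
    "BASE_ORDER",
    "EnsembleConfig",
    "EnsembleModel",
    "SaliencyMap",
    "MotifWindow",
    "encode_sequences",
    "decode_sequences",
    "train_ensemble",
    "predict",
    "differential_saliency",
    "extract_salient_windows",
    "saliency_gain",
    "predicted_motif_effect",
]

#: Channel order of the one-hot encoding.
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

TASK_NAMES = ("ESC", "DE")


# ---------------------------------------------------------------------------
# encoding

def encode_sequences(seqs: list[str]) -> np.ndarray:
    """One-hot encode equal-length ACGT sequences to (n, 4, length)."""
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    x = np.zeros((len(seqs), 4, length), dtype=np.float32)
    for i, s in enumerate(seqs):
        s = s.upper()
        if len(s) != length:
            raise ValueError("sequences must have uniform length")
        for j, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValueError(f"non-ACGT character {b!r} at position {j}")
            x[i, _BASE_INDEX[b], j] = 1.0
    return x


def decode_sequences(x: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    idx = x.argmax(axis=1)
    return ["".join(BASE_ORDER[i] for i in row) for row in idx]


# ---------------------------------------------------------------------------
# layers

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class _Conv1D(_Layer):
    """Valid-mode 1-d convolution over (n, channels, length)."""

    def __init__(self, in_ch: int, out_ch: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.width = width
        scale = np.sqrt(2.0 / (in_ch * width))
        self.w = (rng.standard_normal((in_ch * width, out_ch)) * scale).astype(np.float64)
        self.b = np.zeros(out_ch)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        w = self.width
        # (n, c, L-w+1, w) -> (n, L-w+1, c*w)
        win = sliding_window_view(x, w, axis=2)
        self._xw = win.transpose(0, 2, 1, 3).reshape(n, length - w + 1, c * w)
        self._in_shape = x.shape
        out = self._xw @ self.w + self.b  # (n, L', out_ch)
        return out.transpose(0, 2, 1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        w = self.width
        gt = g.transpose(0, 2, 1)  # (n, L', out_ch)
        self.grads[0][...] = np.tensordot(self._xw, gt, axes=([0, 1], [0, 1]))
        self.grads[1][...] = gt.sum(axis=(0, 1))
        gxw = (gt @ self.w.T).reshape(n, length - w + 1, c, w)
        gx = np.zeros(self._in_shape)
        for k in range(w):
            gx[:, :, k : k + length - w + 1] += gxw[:, :, :, k].transpose(0, 2, 1)
        return gx


class _ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class _GlobalMaxPool(_Layer):
    """Max over the position axis of (n, channels, length)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._argmax = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, _ = self._shape
        gx = np.zeros(self._shape)
        ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gx[ii, jj, self._argmax] = g
        return gx


class _Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float64)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class _Network:
    """A sequential stack producing two task logits."""

    def __init__(self, layers: list[_Layer], arch_id: str):
        self.layers = layers
        self.arch_id = arch_id

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x  # logits (n, 2)

    def input_gradient(self, x: np.ndarray, out_weights: np.ndarray) -> np.ndarray:
        """Gradient of ``logits @ out_weights`` with respect to the input."""
        self.forward(x)
        g = np.broadcast_to(out_weights, (x.shape[0], 2)).astype(float).copy()
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


# ---------------------------------------------------------------------------
# ensemble

#: (filter width, n filters, n conv layers) for the nine convolutional
#: members; the tenth member is the linear no-hidden-layer baseline.
DEFAULT_ARCHITECTURES: tuple[tuple[int, int, int], ...] = (
    (5, 32, 1), (5, 64, 1), (9, 32, 1), (9, 64, 1),
    (13, 32, 1), (13, 64, 1), (17, 32, 1), (17, 64, 1),
    (9, 32, 2),
)


@dataclass
class EnsembleConfig:
    """Training hyperparameters for the ensemble."""

    epochs: int = 6
    batch_size: int = 128
    learning_rate: float = 5e-3
    val_fraction: float = 0.1
    architectures: tuple[tuple[int, int, int], ...] = DEFAULT_ARCHITECTURES
    seed: int = 0


@dataclass
class EnsembleModel:
    """Ten trained members plus their per-epoch validation losses."""

    members: list[_Network]
    task_names: tuple[str, str] = TASK_NAMES
    training_log: dict[str, list[float]] = field(default_factory=dict)
    input_length: int = 100
    member_val_auroc: dict[str, float] = field(default_factory=dict)

    @property
    def includes_linear_member(self) -> bool:
        return any(m.arch_id == "linear" for m in self.members)

    @property
    def linear_member(self) -> _Network:
        return next(m for m in self.members if m.arch_id == "linear")

    @property
    def conv_members(self) -> list[_Network]:
        return [m for m in self.members if m.arch_id != "linear"]


def _build_member(arch: tuple[int, int, int] | str, input_length: int,
                  rng: np.random.Generator) -> _Network:
    if arch == "linear":
        return _Network(
            [_Flatten(), _Dense(4 * input_length, 2, rng)], "linear"
        )
    width, n_filters, n_layers = arch
    layers: list[_Layer] = [_Conv1D(4, n_filters, width, rng), _ReLU()]
    if n_layers == 2:
        layers += [_Conv1D(n_filters, n_filters, 5, rng), _ReLU()]
    layers += [_GlobalMaxPool(), _Dense(n_filters, 2, rng)]
    return _Network(layers, f"conv_w{width}_f{n_filters}_l{n_layers}")


def _train_member(
    net: _Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: EnsembleConfig,
    rng: np.random.Generator,
) -> list[float]:
    opt = _Adam(net.parameters, config.learning_rate)
    n = len(x_train)
    val_losses: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z = net.forward(xb)
            # binary cross-entropy with logits, mean over batch and tasks
            gz = (_sigmoid(z) - yb) / (len(idx) * 2)
            g = gz
            for layer in reversed(net.layers):
                g = layer.backward(g)
            opt.step(net.gradients)
        zv = net.forward(x_val)
        val_loss = float(
            np.mean(np.logaddexp(0.0, zv) - y_val * zv)
        )
        if not np.isfinite(val_loss):
            raise FloatingPointError("training diverged (non-finite loss)")
        val_losses.append(val_loss)
    return val_losses


def train_ensemble(
    sequences: list[str],
    labels: np.ndarray,
    config: EnsembleConfig | None = None,
) -> EnsembleModel:
    """Train the ten-member ensemble on labeled sequences.

    ``labels`` is the (n, 2) bit matrix (open-in-ESC, open-in-DE). A
    validation fraction is held out for the loss log and per-member AUROC;
    training is fully seeded and deterministic. A member whose loss turns
    non-finite is dropped with a warning.
    """
    config = config or EnsembleConfig()
    x = encode_sequences(sequences).astype(np.float64)
    y = np.asarray(labels, dtype=float)
    if y.shape != (len(x), 2):
        raise ValueError("labels must have shape (n_sequences, 2)")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(x))))
    perm = rng.permutation(len(x))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train, y_train = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    archs: list[tuple[int, int, int] | str] = list(config.architectures) + ["linear"]
    members: list[_Network] = []
    log: dict[str, list[float]] = {}
    auroc: dict[str, float] = {}
    for i, arch in enumerate(archs):
        member_rng = np.random.default_rng((config.seed, i))
        net = _build_member(arch, x.shape[2], member_rng)
        try:
            losses = _train_member(net, x_train, y_train, x_val, y_val, config, member_rng)
        except FloatingPointError as exc:
            warnings.warn(f"member {net.arch_id} aborted: {exc}", stacklevel=2)
            continue
        members.append(net)
        log[net.arch_id] = losses
        pv = _sigmoid(net.forward(x_val))
        scores = []
        for task in range(2):
            if len(np.unique(y_val[:, task])) == 2:
                scores.append(roc_auc_score(y_val[:, task], pv[:, task]))
        auroc[net.arch_id] = float(np.mean(scores)) if scores else float("nan")
    return EnsembleModel(
        members=members,
        training_log=log,
        input_length=x.shape[2],
        member_val_auroc=auroc,
    )


def _check_length(model: EnsembleModel, x: np.ndarray) -> None:
    if x.shape[2] != model.input_length:
        raise ValueError(
            f"sequence length {x.shape[2]} differs from training length "
            f"{model.input_length}"
        )


def predict(model: EnsembleModel, sequences: list[str]) -> np.ndarray:
    """Ensemble openness probabilities, shape (n, 2) = (p_ESC, p_DE)."""
    x = encode_sequences(sequences).astype(np.float64)
    _check_length(model, x)
    probs = np.stack([_sigmoid(m.forward(x)) for m in model.members])
    return probs.mean(axis=0)


# ---------------------------------------------------------------------------
# saliency

@dataclass
class SaliencyMap:
    """Per-position, per-base importance of one sequence for an objective.

    ``scores`` has shape (4, length) in the A,C,G,T channel order; after
    multiplication by the one-hot input only the observed base of each
    position is nonzero.
    """

    sequence: str
    scores: np.ndarray
    objective: str = "DE_minus_ESC"

    def position_scores(self) -> np.ndarray:
        return self.scores.sum(axis=0)


@dataclass(frozen=True)
class MotifWindow:
    """A fixed-width high-saliency window aggregated across sequences."""

    window_seq: str
    score: float
    support_count: int


_OBJECTIVES = {
    "ESC": np.array([1.0, 0.0]),
    "DE": np.array([0.0, 1.0]),
    "DE_minus_ESC": np.array([-1.0, 1.0]),
}


def differential_saliency(
    model: EnsembleModel,
    sequences: list[str],
    n_noise_samples: int = 25,
    noise_sd: float = 0.1,
    objective: str = "DE_minus_ESC",
    members: list[_Network] | None = None,
    seed: int = 0,
    member_weights: np.ndarray | None = None,
) -> list[SaliencyMap]:
    """Smoothed-gradient saliency of the cell-type-difference objective.

    For each member the gradient of the objective (a fixed combination of
    the two task *logits*; the default is the DE logit minus the ESC logit)
    with respect to the input is averaged over ``n_noise_samples`` Gaussian
    perturbations of the one-hot input, multiplied elementwise by the clean
    input, then averaged across members (uniformly unless
    ``member_weights`` is given).
    """
    if n_noise_samples < 1:
        raise ValueError("n_noise_samples must be >= 1")
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {sorted(_OBJECTIVES)}")
    out_w = _OBJECTIVES[objective]
    nets = members if members is not None else model.members
    if member_weights is None:
        weights = np.full(len(nets), 1.0 / len(nets))
    else:
        weights = np.asarray(member_weights, dtype=float)
        weights = weights / weights.sum()
    x = encode_sequences(sequences).astype(np.float64)
    _check_length(model, x)
    rng = np.random.default_rng(seed)
    total = np.zeros_like(x)
    for net, wt in zip(nets, weights):
        grad = np.zeros_like(x)
        for _ in range(n_noise_samples):
            noisy = x + rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else x
            grad += net.input_gradient(noisy, out_w)
        total += wt * (grad / n_noise_samples)
    total *= x  # gradient x input: mask bases absent from the sequence
    return [
        SaliencyMap(sequence=s, scores=total[i], objective=objective)
        for i, s in enumerate(sequences)
    ]


def _window_scores(maps: list[SaliencyMap], window: int) -> list[tuple[float, int, int]]:
    """(score, seq_idx, start) for every window of every map."""
    out = []
    for i, sm in enumerate(maps):
        pos = sm.position_scores()
        if len(pos) < window:
            raise ValueError("window longer than sequence")
        sums = np.convolve(pos, np.ones(window), mode="valid") / window
        out.extend((float(s), i, j) for j, s in enumerate(sums))
    return out


def extract_salient_windows(
    maps: list[SaliencyMap],
    window: int = 10,
    top_k: int = 20,
) -> list[MotifWindow]:
    """Top saliency windows across sequences, as candidate motifs.

    Windows are ranked globally by mean within-window saliency; a window
    overlapping an already-selected higher-scoring window of the same
    sequence is skipped (greedy non-redundancy). Ties break by (sequence
    index, start). Identical window strings among the selected top_k are
    aggregated: support is the number of occurrences, score their mean.
    """
    if not maps:
        raise ValueError("no saliency maps")
    scored = _window_scores(maps, window)
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken: dict[int, list[int]] = {}
    selected: list[tuple[float, int, int]] = []
    for score, i, j in scored:
        if any(abs(j - j0) < window for j0 in taken.get(i, ())):
            continue
        selected.append((score, i, j))
        taken.setdefault(i, []).append(j)
        if len(selected) >= top_k:
            break
    agg: dict[str, list[float]] = {}
    order: list[str] = []
    for score, i, j in selected:
        s = maps[i].sequence[j : j + window]
        if s not in agg:
            order.append(s)
        agg.setdefault(s, []).append(score)
    return [
        MotifWindow(window_seq=s, score=float(np.mean(agg[s])), support_count=len(agg[s]))
        for s in order
    ]


def saliency_gain(
    deep_maps: list[SaliencyMap],
    linear_maps: list[SaliencyMap],
    window: int = 10,
    top_k: int = 20,
) -> list[MotifWindow]:
    """Windows ranked by saliency gained from the convolutional members.

    The gain of a window is its mean saliency under the hidden-layer
    members minus under the linear member; high-gain windows mark motifs
    whose importance arises from learned motif-motif relationships rather
    than additive content.
    """
    if len(deep_maps) != len(linear_maps) or any(
        d.sequence != l.sequence for d, l in zip(deep_maps, linear_maps)
    ):
        raise ValueError("deep and linear maps must cover identical sequences")
    gains = [
        SaliencyMap(sequence=d.sequence, scores=d.scores - l.scores, objective=d.objective)
        for d, l in zip(deep_maps, linear_maps)
    ]
    return extract_salient_windows(gains, window=window, top_k=top_k)


def predicted_motif_effect(
    model: EnsembleModel,
    designs: list[DesignedSequence],
    min_backgrounds: int = 3,
) -> dict[str, float]:
    """Model-predicted differential effect per motif across backgrounds.

    Designs are grouped by their motif content (sorted placed motif ids);
    the predicted effect is the mean of (p_DE - p_ESC) over the group's
    backgrounds — the same estimator as the measured stage-1 effect, so the
    two can be correlated directly. Groups with fewer than
    ``min_backgrounds`` backgrounds are skipped with a warning.
    """
    groups: dict[str, list[DesignedSequence]] = {}
    for d in designs:
        ids = sorted(d.motif_copy_counts())
        if not ids:
            continue
        groups.setdefault("+".join(ids), []).append(d)
    effects: dict[str, float] = {}
    for unit, group in sorted(groups.items()):
        if len(group) < min_backgrounds:
            warnings.warn(
                f"motif {unit}: only {len(group)} backgrounds, skipped", stacklevel=2
            )
            continue
        probs = predict(model, [d.variable_seq for d in group])
        effects[unit] = float((probs[:, 1] - probs[:, 0]).mean())
    return effects
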