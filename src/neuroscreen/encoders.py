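"""Frozen feature extractors for landmark trajectories and voice features.

The landmark encoder follows the semantics-guided skeleton-network family:
each joint's position+velocity is embedded, a learned per-joint (semantic)
embedding is added, messages are passed over the skeleton adjacency, joints
are pooled per frame, and a temporal convolution with mean+std pooling yields
one fixed-length feature per sequence (128-dim in the published
configuration).  The voice encoder follows the crossed time-delay family:
parallel temporal convolutions with different context widths over the 25 MFCC
channels, statistics-pooled and fused to one 512-dim feature.

During main training these encoders are frozen — only the subnetworks,
protocol heads and aggregator learn — which is why sessions are encoded once
and cached.  A pretraining harness (classification or regression on a proxy
corpus) is provided for producing encoder weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nnet
from .nnet import Tensor
from .protocols import BODY, FACE, HAND, JOINT_COUNTS, MFCC_CHANNELS

# ---------------------------------------------------------------------------
# Skeleton adjacency
# ---------------------------------------------------------------------------

#: 13 body joints after dropping the eye/ear points: index order
BODY_JOINT_NAMES = (
    "nose",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)

_BODY_EDGES = [
    (0, 1), (0, 2), (1, 2),          # nose-shoulders, clavicle
    (1, 3), (3, 5), (2, 4), (4, 6),  # arms
    (1, 7), (2, 8), (7, 8),          # torso
    (7, 9), (9, 11), (8, 10), (10, 12),  # legs
]


def _chain(indices) -> list[tuple[int, int]]:
    idx = list(indices)
    return list(zip(idx[:-1], idx[1:]))


def _cycle(indices) -> list[tuple[int, int]]:
    idx = list(indices)
    return _chain(idx) + [(idx[-1], idx[0])]


def _face_edges() -> list[tuple[int, int]]:
    # the standard 68-point groups: jaw, brows, nose bridge+base, eyes, lips
    edges = []
    edges += _chain(range(0, 17))        # jawline
    edges += _chain(range(17, 22))       # right eyebrow
    edges += _chain(range(22, 27))       # left eyebrow
    edges += _chain(range(27, 31))       # nose bridge
    edges += _chain(range(31, 36))       # nose base
    edges += _cycle(range(36, 42))       # right eye
    edges += _cycle(range(42, 48))       # left eye
    edges += _cycle(range(48, 60))       # outer lip
    edges += _cycle(range(60, 68))       # inner lip
    return edges


def _hand_edges() -> list[tuple[int, int]]:
    # two independent 21-point hands: wrist root, five 4-joint finger chains
    edges = []
    for base in (0, 21):
        for finger in range(5):
            root = base + 1 + 4 * finger
            edges.append((base, root))
            edges += _chain(range(root, root + 4))
    return edges


_PART_EDGES = {BODY: _BODY_EDGES, FACE: _face_edges(), HAND: _hand_edges()}


def skeleton_adjacency(part: str) -> np.ndarray:
    """Symmetrically normalized adjacency (with self-loops) for one part."""
    n = JOINT_COUNTS[part]
    a = np.eye(n)
    for i, j in _PART_EDGES[part]:
        a[i, j] = a[j, i] = 1.0
    deg = a.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkEncoderConfig:
    part: str
    in_channels: int = 4          # positions + velocities
    out_dim: int = 128
    embed_dim: int = 32
    graph_rounds: int = 2
    velocity_gain: float = 30.0   # frame differences -> units/second at 30 fps
    temporal_stride: int = 4      # stride of the frame-level conv
    temporal_channels: int = 64
    temporal_kernel: int = 5
    size: str = "full"

    @classmethod
    def tiny(cls, part: str, out_dim: int = 16) -> "LandmarkEncoderConfig":
        return cls(part=part, out_dim=out_dim, embed_dim=8, graph_rounds=1,
                   temporal_stride=2, temporal_channels=8, temporal_kernel=3,
                   size="tiny")


@dataclass(frozen=True)
class VoiceEncoderConfig:
    in_channels: int = MFCC_CHANNELS
    out_dim: int = 512
    branch_channels: int = 64
    context_sizes: tuple[int, ...] = (3, 7, 15)
    size: str = "full"

    def __post_init__(self) -> None:
        if len(set(self.context_sizes)) < 2:
            raise ValueError("need at least two distinct context sizes")

    @classmethod
    def tiny(cls, out_dim: int = 32) -> "VoiceEncoderConfig":
        return cls(out_dim=out_dim, branch_channels=8, context_sizes=(3, 5),
                   size="tiny")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


def _stats_pool(x: Tensor, axis: int) -> Tensor:
    """Concatenate mean and standard deviation over one axis."""
    m = x.mean(axis=axis, keepdims=True)
    d = x - m
    v = (d * d).mean(axis=axis)
    s = (v + 1e-8) ** 0.5
    return nnet.concat([x.mean(axis=axis), s], axis=-1)


class LandmarkEncoder(nnet.Module):
    """Graph message passing over the skeleton, then temporal conv + pooling."""

    def __init__(self, config: LandmarkEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.embed_dim
        self.adjacency = skeleton_adjacency(config.part)
        self.joint_embed = nnet.Linear(config.in_channels, d, rng)
        # semantic embedding: one learned vector per joint index
        self.semantic = Tensor(
            rng.normal(0.0, 0.1, size=(JOINT_COUNTS[config.part], d)),
            requires_grad=True,
        )
        self.graph_weights = [nnet.Linear(d, d, rng) for _ in range(config.graph_rounds)]
        self.temporal = nnet.Conv1d(d, config.temporal_channels,
                                    config.temporal_kernel, rng,
                                    stride=config.temporal_stride)
        # mean+std pooled joint features and conv features feed the head:
        # the std terms carry oscillation energy (tremor) that frame
        # averaging alone would cancel
        self.head = nnet.Linear(
            2 * config.temporal_channels + 2 * d, config.out_dim, rng
        )

    def forward(self, x: Tensor) -> Tensor:
        """(B, F, J, 4) -> (B, out_dim)."""
        cfg = self.config
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        batch, frames, joints, channels = x.shape
        if joints != JOINT_COUNTS[cfg.part]:
            raise ValueError(f"expected {JOINT_COUNTS[cfg.part]} joints, got {joints}")
        if channels == 4 and cfg.velocity_gain != 1.0:
            # frame differences are tiny next to unit-RMS positions; rescale
            # them to units/second so the embedding sees both
            gain = np.ones(4)
            gain[2:] = cfg.velocity_gain
            x = x * Tensor(gain)
        h = self.joint_embed(x).relu() + self.semantic          # (B,F,J,d)
        adj = Tensor(self.adjacency)
        for linear in self.graph_weights:
            h = h + (adj @ linear(h)).relu()                    # residual message round
        h = h.mean(axis=2)                                      # pool joints: (B,F,d)
        if frames < cfg.temporal_kernel:
            raise ValueError("sequence too short for the temporal kernel")
        frame_stats = _stats_pool(h, axis=1)                    # (B,2d)
        conv = self.temporal(h.transpose(0, 2, 1)).relu()       # (B,C,T)
        conv_stats = _stats_pool(conv, axis=2)                  # (B,2C)
        return self.head(nnet.concat([conv_stats, frame_stats], axis=-1))


class VoiceEncoder(nnet.Module):
    """Parallel temporal-conv branches with different context widths, fused."""

    def __init__(self, config: VoiceEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config.branch_channels
        self.branches = [
            nnet.Conv1d(config.in_channels, c, k, rng, stride=2)
            for k in config.context_sizes
        ]
        # branch statistics plus a direct per-channel mean+std skip path
        self.head = nnet.Linear(
            2 * c * len(config.context_sizes) + 2 * config.in_channels,
            config.out_dim, rng,
        )

    def forward(self, x: Tensor) -> Tensor:
        """(B, F, 25) -> (B, out_dim)."""
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[2] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[2]}"
            )
        # cepstral mean normalization: the conv branches see per-channel
        # temporally centred features (dynamics), while the skip path keeps
        # the raw per-channel mean+std (speaker/timbre statistics)
        centered = x - x.mean(axis=1, keepdims=True)
        xt = centered.transpose(0, 2, 1)                        # (B,25,F)
        pooled = [_stats_pool(branch(xt).relu(), axis=2) for branch in self.branches]
        pooled.append(_stats_pool(x, axis=1))
        return self.head(nnet.concat(pooled, axis=-1))


def encode_landmarks(dyn: np.ndarray, model: LandmarkEncoder) -> np.ndarray:
    """Encode one staticized (F, J, 4) dynamic representation to a feature vector."""
    was_training = model.training
    model.eval()
    try:
        with nnet.no_grad():
            out = model(Tensor(dyn)).data
    finally:
        model.train(was_training)
    return out.reshape(-1)


def encode_voice(values: np.ndarray, model: VoiceEncoder) -> np.ndarray:
    """Encode one prepared (F, 25) MFCC table to a feature vector."""
    was_training = model.training
    model.eval()
    try:
        with nnet.no_grad():
            out = model(Tensor(values)).data
    finally:
        model.train(was_training)
    return out.reshape(-1)


# ---------------------------------------------------------------------------
# Digests and checkpoints
# ---------------------------------------------------------------------------


def parameter_digest(model: nnet.Module) -> str:
    """SHA-256 over all parameter/buffer bytes — the frozen-weights contract."""
    h = hashlib.sha256()
    for name in sorted(state := model.named_state()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name], dtype=np.float64).tobytes())
    return h.hexdigest()


def config_digest(config) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(path, model: nnet.Module, config) -> None:
    state = {k: np.asarray(v) for k, v in model.named_state().items()}
    np.savez(path, __config_digest__=config_digest(config), **state)


def load_checkpoint(path, model: nnet.Module, config) -> None:
    with np.load(path, allow_pickle=False) as data:
        digest = str(data["__config_digest__"])
        if digest != config_digest(config):
            raise ValueError(
                f"checkpoint config digest {digest} does not match {config_digest(config)}"
            )
        model.load_state({k: data[k] for k in data.files if k != "__config_digest__"})


# ---------------------------------------------------------------------------
# Pretraining harness
# ---------------------------------------------------------------------------


@dataclass
class PretrainTask:
    """A proxy corpus for encoder pretraining.

    ``inputs``: (n, ...) array of encoder-ready samples (dynamic landmark
    representations or MFCC tables, all the same shape).  ``targets``: class
    indices (classification) or real values (regression).
    """

    inputs: np.ndarray
    targets: np.ndarray
    kind: str  # "classification" | "regression"

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "regression"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs/targets length mismatch")


def pretrain_encoder(
    encoder: nnet.Module,
    task: PretrainTask,
    *,
    epochs: int = 20,
    batch_size: int = 8,
    learning_rate: float = 1e-3,
    val_fraction: float = 0.25,
    patience: int = 5,
    seed: int = 0,
) -> dict:
    """Train an encoder plus a task head; early-stop on the validation metric.

    Returns a history dict with per-epoch train loss and validation metric
    (accuracy for classification, RMSE for regression); the encoder is left
    holding the weights of the best validation epoch.
    """
    rng = np.random.default_rng(seed)
    n = len(task.inputs)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("corpus too small for the requested validation fraction")

    out_dim = encoder.config.out_dim
    if task.kind == "classification":
        n_classes = int(task.targets.max()) + 1
        head = nnet.Linear(out_dim, n_classes, rng)
    else:
        head = nnet.Linear(out_dim, 1, rng)

    params = encoder.parameters() + head.parameters()
    opt = nnet.Adam(params, lr=learning_rate)
    history = {"train_loss": [], "val_metric": []}
    best_metric, best_state, stale = -np.inf, None, 0

    def val_metric() -> float:
        encoder.eval()
        with nnet.no_grad():
            z = head(encoder(Tensor(task.inputs[val_idx]))).data
        encoder.train()
        if task.kind == "classification":
            return float(np.mean(z.argmax(axis=1) == task.targets[val_idx]))
        rmse = float(np.sqrt(np.mean((z.ravel() - task.targets[val_idx]) ** 2)))
        return -rmse  # maximize

    for _ in range(epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), batch_size):
            idx = perm[i:i + batch_size]
            z = head(encoder(Tensor(task.inputs[idx])))
            if task.kind == "classification":
                onehot = np.eye(n_classes)[task.targets[idx]]
                loss = nnet.softmax_cross_entropy(z, onehot)
            else:
                err = z.reshape(-1) - Tensor(task.targets[idx].astype(float))
                loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        metric = val_metric()
        history["train_loss"].append(float(np.mean(losses)))
        history["val_metric"].append(
            metric if task.kind == "classification" else -metric
        )
        if metric > best_metric:
            best_metric, stale = metric, 0
            best_state = {k: v.copy() for k, v in encoder.named_state().items()}
        else:
            stale += 1
            if stale >= patience:
                break
    if best_state is not None:
        encoder.load_state(best_state)
    encoder.eval()
    return history
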