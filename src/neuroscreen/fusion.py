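"""Per-protocol subnetworks, protocol-normality heads, and the feature aggregator.

Each protocol's encoder outputs (one per camera and body part, or one voice
feature) are concatenated in a fixed order — cameras as configured (center
then left by default), parts body, face, hand — into an N_s-vector.  A
two-block (linear, batch-norm, ReLU, dropout) subnetwork maps N_s -> 64 -> 8;
a linear head on the 8-dim protocol feature scores protocol normality.  The
aggregator concatenates all protocol features (8*N_p), applies one
(linear, batch-norm, ReLU, dropout) block to 8 dims and two disease-specific
linear heads of 2 logits each (stroke, Parkinson's).

A protocol whose payloads are missing (occluded face, failed extraction) is
masked: it contributes an exactly-zero 8-vector to the aggregator and its
normality loss is skipped.  Subnetwork batch statistics are computed over the
present rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nnet
from . import protocols as P
from .data_model import Camera, PipelineConfig, ProtocolRecording, SubjectSession
from .encoders import (
    LandmarkEncoder,
    LandmarkEncoderConfig,
    VoiceEncoder,
    VoiceEncoderConfig,
    encode_landmarks,
    encode_voice,
)
from .nnet import Tensor
from .preprocessing import (
    augment_landmarks,
    dynamic_representation,
    normalize_landmarks,
    prepare_mfcc,
)
from .staticizer import staticize

PART_ORDER = (P.BODY, P.FACE, P.HAND)


@dataclass(frozen=True)
class SubnetworkSpec:
    input_dim: int
    hidden_dim: int = 64
    output_dim: int = 8
    dropout: float = 0.3


@dataclass(frozen=True)
class AggregatorSpec:
    n_protocols: int
    protocol_dim: int = 8
    hidden_dim: int = 8
    dropout: float = 0.3

    @property
    def input_dim(self) -> int:
        return self.protocol_dim * self.n_protocols


def subnetwork_input_dim(protocol_id: int, config: PipelineConfig) -> int:
    """N_s: N_f * N_c * N_j for landmark protocols, the voice dim otherwise."""
    info = P.PROTOCOLS[protocol_id]
    if info.has_voice:
        return config.voice_feature_dim
    n_cams = len(config.cameras_for_landmarks)
    return config.landmark_feature_dim * n_cams * len(info.landmark_parts)


def protocol_input(
    features: dict[tuple, np.ndarray],
    protocol_id: int,
    config: PipelineConfig,
) -> np.ndarray:
    """Concatenate one protocol's encoder outputs into its N_s-vector.

    ``features`` maps (part, camera) -> landmark feature for landmark
    protocols, or ("voice",) -> voice feature.  Raises KeyError listing the
    missing entry if a required feature is absent.
    """
    info = P.PROTOCOLS[protocol_id]
    if info.has_voice:
        return np.asarray(features[("voice",)], dtype=np.float64)
    pieces = []
    for camera in config.cameras_for_landmarks:
        for part in PART_ORDER:
            if part not in info.landmark_parts:
                continue
            key = (part, camera)
            if key not in features:
                raise KeyError(f"protocol {protocol_id}: missing feature for {key}")
            pieces.append(np.asarray(features[key], dtype=np.float64))
    return np.concatenate(pieces)


class Subnetwork(nnet.Module):
    """N_s -> 64 -> 8 with a 2-logit normality head on the 8-dim feature."""

    def __init__(self, spec: SubnetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.block1 = nnet.Sequential(
            nnet.Linear(spec.input_dim, spec.hidden_dim, rng),
            nnet.BatchNorm1d(spec.hidden_dim),
            nnet.ReLU(),
            nnet.Dropout(spec.dropout, rng),
        )
        self.block2 = nnet.Sequential(
            nnet.Linear(spec.hidden_dim, spec.output_dim, rng),
            nnet.BatchNorm1d(spec.output_dim),
            nnet.ReLU(),
            nnet.Dropout(spec.dropout, rng),
        )
        self.normality_head = nnet.Linear(spec.output_dim, 2, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"expected input dim {self.spec.input_dim}, got {x.shape[-1]}"
            )
        return self.block2(self.block1(x))

    def forward_with_normality(self, x: Tensor) -> tuple[Tensor, Tensor]:
        feat = self.forward(x)
        return feat, self.normality_head(feat)


class Aggregator(nnet.Module):
    """8*N_p -> 8 block plus two disease-specific 2-logit heads."""

    def __init__(self, spec: AggregatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.block = nnet.Sequential(
            nnet.Linear(spec.input_dim, spec.hidden_dim, rng),
            nnet.BatchNorm1d(spec.hidden_dim),
            nnet.ReLU(),
            nnet.Dropout(spec.dropout, rng),
        )
        self.stroke_head = nnet.Linear(spec.hidden_dim, 2, rng)
        self.pd_head = nnet.Linear(spec.hidden_dim, 2, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if x.shape[-1] != self.spec.input_dim:
            raise ValueError(f"expected input dim {self.spec.input_dim}, got {x.shape[-1]}")
        h = self.block(x)
        return self.stroke_head(h), self.pd_head(h)


def _scatter_rows(x: Tensor, rows: np.ndarray, batch: int) -> Tensor:
    """Place (m, d) rows into a zero (batch, d) tensor (autograd-aware)."""
    data = np.zeros((batch, x.shape[-1]))
    data[rows] = x.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[rows])

    return Tensor._result(data, (x,), backward)


@dataclass
class SessionFeatures:
    """Cached encoder outputs for one session: one N_s-vector per protocol.

    ``inputs[pid]`` is None when the protocol is masked (missing payload or
    uncertain label upstream); the mask mirrors that.
    """

    subject_id: str
    inputs: dict[int, np.ndarray | None]

    def mask(self, active: tuple[int, ...]) -> np.ndarray:
        return np.array([self.inputs[pid] is not None for pid in active])


class ScreeningModel(nnet.Module):
    """Frozen encoders + trainable subnetworks and aggregator.

    ``active_protocols`` supports the single-protocol/subset ablations: only
    those subnetworks exist and the aggregator input shrinks to 8 * N_p.
    """

    def __init__(
        self,
        config: PipelineConfig,
        rng: np.random.Generator,
        active_protocols: tuple[int, ...] = P.PROTOCOL_IDS,
    ):
        super().__init__()
        self.config = config
        self.active_protocols = tuple(sorted(active_protocols))
        if not self.active_protocols:
            raise ValueError("need at least one active protocol")

        tiny = config.encoder_size == "tiny"
        self.landmark_encoders = {}
        for part in PART_ORDER:
            cfg = (
                LandmarkEncoderConfig.tiny(part, out_dim=config.landmark_feature_dim)
                if tiny
                else LandmarkEncoderConfig(part=part, out_dim=config.landmark_feature_dim)
            )
            enc = LandmarkEncoder(cfg, rng)
            enc.eval()
            for p in enc.parameters():
                p.requires_grad = False
            self.landmark_encoders[part] = enc
        vcfg = (
            VoiceEncoderConfig.tiny(out_dim=config.voice_feature_dim)
            if tiny
            else VoiceEncoderConfig(out_dim=config.voice_feature_dim)
        )
        self.voice_encoder = VoiceEncoder(vcfg, rng)
        self.voice_encoder.eval()
        for p in self.voice_encoder.parameters():
            p.requires_grad = False

        self.subnetworks = {
            pid: Subnetwork(
                SubnetworkSpec(
                    input_dim=subnetwork_input_dim(pid, config),
                    hidden_dim=config.subnetwork_hidden_dim,
                    output_dim=config.protocol_feature_dim,
                    dropout=config.dropout,
                ),
                rng,
            )
            for pid in self.active_protocols
        }
        self.aggregator = Aggregator(
            AggregatorSpec(
                n_protocols=len(self.active_protocols),
                protocol_dim=config.protocol_feature_dim,
                hidden_dim=config.aggregator_hidden_dim,
                dropout=config.dropout,
            ),
            rng,
        )

    # Module.modules() only walks attributes; expose the dict values too.
    def modules(self):
        yield self
        for enc in self.landmark_encoders.values():
            yield from enc.modules()
        yield from self.voice_encoder.modules()
        for sub in self.subnetworks.values():
            yield from sub.modules()
        yield from self.aggregator.modules()

    def _collect_state(self, state, prefix=""):
        for part, enc in self.landmark_encoders.items():
            enc._collect_state(state, prefix=f"{prefix}landmark_encoders.{part}.")
        self.voice_encoder._collect_state(state, prefix=f"{prefix}voice_encoder.")
        for pid, sub in self.subnetworks.items():
            sub._collect_state(state, prefix=f"{prefix}subnetworks.{pid}.")
        self.aggregator._collect_state(state, prefix=f"{prefix}aggregator.")

    def load_state(self, state, prefix=""):
        for part, enc in self.landmark_encoders.items():
            enc.load_state(state, prefix=f"{prefix}landmark_encoders.{part}.")
        self.voice_encoder.load_state(state, prefix=f"{prefix}voice_encoder.")
        for pid, sub in self.subnetworks.items():
            sub.load_state(state, prefix=f"{prefix}subnetworks.{pid}.")
        self.aggregator.load_state(state, prefix=f"{prefix}aggregator.")

    def trainable_parameters(self) -> list[Tensor]:
        params = []
        for sub in self.subnetworks.values():
            params += sub.parameters()
        params += self.aggregator.parameters()
        return params

    def encoder_modules(self) -> list[nnet.Module]:
        return [*self.landmark_encoders.values(), self.voice_encoder]

    # ------------------------------------------------------------------
    # Feature extraction (frozen path)
    # ------------------------------------------------------------------

    def _encode_recording(self, rec: ProtocolRecording, augment_rng=None):
        out = {}
        for part, seq in rec.landmarks.items():
            params = self.config.staticizer[part]
            if augment_rng is not None:
                seq = augment_landmarks(seq, self.config.augmentation, augment_rng)
            seq = normalize_landmarks(staticize(seq, params))
            dyn = dynamic_representation(seq)
            out[(part, rec.camera)] = encode_landmarks(dyn, self.landmark_encoders[part])
        if rec.voice is not None:
            prepared = prepare_mfcc(rec.voice, self.config.mfcc_target_frames)
            out[("voice",)] = encode_voice(prepared.array, self.voice_encoder)
        return out

    def session_features(
        self, session: SubjectSession, augment_rng: np.random.Generator | None = None
    ) -> SessionFeatures:
        """Run the frozen encoders over a session once; cacheable.

        With ``augment_rng`` set, landmark sequences are randomly augmented
        before encoding (training-time variants).
        """
        cfg = self.config
        inputs: dict[int, np.ndarray | None] = {}
        for pid in self.active_protocols:
            info = P.PROTOCOLS[pid]
            features: dict[tuple, np.ndarray] = {}
            for rec in session.recordings_of(pid):
                if info.has_voice:
                    if rec.camera == cfg.camera_for_voice and rec.voice is not None:
                        features.update(self._encode_recording(rec))
                elif rec.camera in cfg.cameras_for_landmarks:
                    wanted = {p: s for p, s in rec.landmarks.items()
                              if p in info.landmark_parts}
                    rec_sub = ProtocolRecording(pid, rec.camera, wanted)
                    features.update(self._encode_recording(rec_sub, augment_rng))
            try:
                inputs[pid] = protocol_input(features, pid, cfg)
            except KeyError:
                inputs[pid] = None  # missing modality -> masked protocol
        return SessionFeatures(session.subject_id, inputs)

    # ------------------------------------------------------------------
    # Trainable forward
    # ------------------------------------------------------------------

    def forward_batch(self, batch: list[SessionFeatures]):
        """Forward a batch of cached features.

        Returns (stroke_logits (B,2), pd_logits (B,2),
        normality_logits: {pid: (rows, (m,2) Tensor)}, mask (B, N_p)).
        Masked protocols contribute exactly-zero 8-dim features.
        """
        batch_size = len(batch)
        mask = np.stack([sf.mask(self.active_protocols) for sf in batch])
        protocol_feats = []
        normality: dict[int, tuple[np.ndarray, Tensor]] = {}
        for j, pid in enumerate(self.active_protocols):
            rows = np.flatnonzero(mask[:, j])
            if rows.size == 0:
                protocol_feats.append(
                    Tensor(np.zeros((batch_size, self.config.protocol_feature_dim)))
                )
                continue
            x = Tensor(np.stack([batch[i].inputs[pid] for i in rows]))
            feat, logits = self.subnetworks[pid].forward_with_normality(x)
            normality[pid] = (rows, logits)
            protocol_feats.append(_scatter_rows(feat, rows, batch_size))
        stroke_logits, pd_logits = self.aggregator(nnet.concat(protocol_feats, axis=-1))
        return stroke_logits, pd_logits, normality, mask


def aggregate(
    protocol_features: np.ndarray,
    missing_mask: np.ndarray,
    aggregator: Aggregator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse an (N_p, 8) protocol-feature table into the two disease logit pairs.

    Convenience single-sample entry point: masked protocols (mask False) are
    zero-imputed, both heads are always computed.
    """
    feats = np.where(np.asarray(missing_mask)[:, None], protocol_features, 0.0)
    was_training = aggregator.training
    aggregator.eval()
    try:
        with nnet.no_grad():
            stroke, pd = aggregator(Tensor(feats.reshape(1, -1)))
    finally:
        aggregator.train(was_training)
    return stroke.data.ravel(), pd.data.ravel()
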