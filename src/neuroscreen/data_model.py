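"""Core domain types: sequences, recordings, sessions, pipeline configuration.

Coordinates are kept in raw image units; centring/scaling is an explicit
preprocessing step so that I/O stays lossless.  A missing modality (a face
occluded by a mask, a failed extraction) is an explicit absence — the
recording simply does not carry that payload — never a NaN-filled array.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from . import protocols as P
from .staticizer import PART_PARAMS, StaticizerParams, is_outlier, tiny_part_params


class Camera(str, enum.Enum):
    CENTER = "center"
    LEFT = "left"
    RIGHT = "right"
    TOP = "top"


class Disease(str, enum.Enum):
    HC = "HC"
    STROKE = "stroke"
    PD = "PD"


class ProtocolLabel(str, enum.Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"
    UNCERTAIN = "uncertain"


class Site(str, enum.Enum):
    """Recruiting hospital; only affects training-time sampling weights."""

    KUAH = "KUAH"
    SUSH = "SUSH"


#: the four body keypoints of the 17-point detector that overlap with the face
#: landmarks and are therefore excluded, leaving the 13 modeled body points
EXCLUDED_BODY_KEYPOINTS = ("left_eye", "right_eye", "left_ear", "right_ear")


@dataclass(frozen=True)
class LandmarkSequence:
    """2-D landmark trajectory of one body part: F x J x 2 (image-plane x, y)."""

    part: str
    array: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=np.float64)
        object.__setattr__(self, "array", arr)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError(f"expected F x J x 2 array, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("need at least one frame")
        expected = P.JOINT_COUNTS.get(self.part)
        if expected is None:
            raise ValueError(f"unknown part {self.part!r}")
        if arr.shape[1] != expected:
            raise ValueError(
                f"{self.part} sequences carry {expected} joints, got {arr.shape[1]}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("non-finite coordinates")

    @property
    def frames(self) -> int:
        return self.array.shape[0]

    @property
    def joints(self) -> int:
        return self.array.shape[1]

    @property
    def coords(self) -> np.ndarray:
        return self.array


@dataclass(frozen=True)
class VoiceFeatureSequence:
    """Per-frame MFCC feature table: F x 25."""

    array: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=np.float64)
        object.__setattr__(self, "array", arr)
        if arr.ndim != 2:
            raise ValueError(f"expected F x C array, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite MFCC values")

    @property
    def frames(self) -> int:
        return self.array.shape[0]

    @property
    def channels(self) -> int:
        return self.array.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.array


@dataclass(frozen=True)
class ProtocolRecording:
    """All payloads of one (protocol, camera) pair.

    ``landmarks`` maps part name -> LandmarkSequence for the parts that were
    actually extracted; a part listed for the protocol but absent here is a
    missing modality.  Voice protocols may carry one VoiceFeatureSequence.
    """

    protocol_id: int
    camera: Camera
    landmarks: dict[str, LandmarkSequence] = field(default_factory=dict)
    voice: VoiceFeatureSequence | None = None

    def __post_init__(self) -> None:
        if self.protocol_id not in P.PROTOCOLS:
            raise ValueError(f"protocol_id must be 1..15, got {self.protocol_id}")
        for part, seq in self.landmarks.items():
            if seq.part != part:
                raise ValueError(f"landmark dict key {part!r} != sequence part {seq.part!r}")

    def present(self, modality: str) -> bool:
        if modality == P.VOICE:
            return self.voice is not None
        return modality in self.landmarks


@dataclass(frozen=True)
class SubjectSession:
    """One subject's full examination: recordings plus disease/protocol labels."""

    subject_id: str
    disease_label: Disease
    protocol_labels: tuple[ProtocolLabel, ...]
    recordings: tuple[ProtocolRecording, ...]
    site: Site = Site.KUAH

    def __post_init__(self) -> None:
        if len(self.protocol_labels) != P.N_PROTOCOLS:
            raise ValueError(
                f"need {P.N_PROTOCOLS} protocol labels, got {len(self.protocol_labels)}"
            )

    def label_of(self, protocol_id: int) -> ProtocolLabel:
        return self.protocol_labels[protocol_id - 1]

    def recordings_of(self, protocol_id: int) -> tuple[ProtocolRecording, ...]:
        return tuple(r for r in self.recordings if r.protocol_id == protocol_id)

    @property
    def any_abnormal(self) -> bool:
        return any(l is ProtocolLabel.ABNORMAL for l in self.protocol_labels)


@dataclass(frozen=True)
class AugmentationRanges:
    """Training-time landmark augmentation: rotation (deg), scale (%),
    translation (% of coordinate extent).  Identity must be reachable."""

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    scale_pct: tuple[float, float] = (70.0, 150.0)
    translation_pct: tuple[float, float] = (-20.0, 20.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("rotation_deg", self.rotation_deg),
            ("scale_pct", self.scale_pct),
            ("translation_pct", self.translation_pct),
        ):
            if lo > hi:
                raise ValueError(f"{name} interval not well-ordered: {(lo, hi)}")
        if not self.rotation_deg[0] <= 0.0 <= self.rotation_deg[1]:
            raise ValueError("rotation range must contain 0 deg")
        if not self.scale_pct[0] <= 100.0 <= self.scale_pct[1]:
            raise ValueError("scale range must contain 100%")
        if not self.translation_pct[0] <= 0.0 <= self.translation_pct[1]:
            raise ValueError("translation range must contain 0%")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, with the published configuration as default."""

    staticizer: dict[str, StaticizerParams] = field(
        default_factory=lambda: dict(PART_PARAMS)
    )
    cameras_for_landmarks: tuple[Camera, ...] = (Camera.CENTER, Camera.LEFT)
    camera_for_voice: Camera = Camera.CENTER
    mfcc_target_frames: int = 2500
    landmark_feature_dim: int = 128
    voice_feature_dim: int = 512
    subnetwork_hidden_dim: int = 64
    protocol_feature_dim: int = 8
    aggregator_hidden_dim: int = 8
    lambda_v: float = 0.1
    label_smoothing: float = 0.1
    dropout: float = 0.3
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 50
    batch_size: int = 8
    oversampling: dict[Site, float] = field(
        default_factory=lambda: {Site.KUAH: 4.0, Site.SUSH: 6.0}
    )
    augmentation: AugmentationRanges = AugmentationRanges()
    n_augment: int = 0
    encoder_size: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (
            self.mfcc_target_frames, self.landmark_feature_dim,
            self.voice_feature_dim, self.subnetwork_hidden_dim,
            self.protocol_feature_dim, self.aggregator_hidden_dim,
            self.epochs, self.batch_size,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions/sizes must be positive")
        if self.lambda_v < 0:
            raise ValueError("lambda_v must be >= 0")
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label smoothing must lie in [0, 0.5)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def paper(cls, **overrides) -> "PipelineConfig":
        return cls(**overrides)

    @classmethod
    def tiny(cls, **overrides) -> "PipelineConfig":
        """Desk-scale preset: short sequences, narrow encoders, CPU-minutes runs."""
        defaults = dict(
            staticizer=tiny_part_params(),
            mfcc_target_frames=200,
            landmark_feature_dim=16,
            voice_feature_dim=32,
            subnetwork_hidden_dim=16,
            encoder_size="tiny",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class Violation:
    subject_id: str
    protocol_id: int | None
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validate_session: violations plus per-protocol usability."""

    subject_id: str
    violations: tuple[Violation, ...]
    usable: dict[int, bool]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_session(session: SubjectSession, config: PipelineConfig) -> ValidationReport:
    """Check one session against the protocol/modality map and length limits.

    Report-based: structural problems become Violation records and mark the
    protocol unusable; they never raise.  (Sequence-level invariants — joint
    counts, finiteness — are enforced at construction, so a session assembled
    from in-memory objects can only violate the cross-recording rules.)
    """
    violations: list[Violation] = []
    usable = {pid: True for pid in P.PROTOCOL_IDS}

    def flag(pid: int | None, kind: str, msg: str) -> None:
        violations.append(Violation(session.subject_id, pid, kind, msg))
        if pid is not None:
            usable[pid] = False

    for pid in P.PROTOCOL_IDS:
        info = P.PROTOCOLS[pid]
        recs = session.recordings_of(pid)
        for rec in recs:
            for part, seq in rec.landmarks.items():
                if part not in info.modalities:
                    flag(pid, "modality_mismatch",
                         f"protocol {pid} does not extract {part} landmarks")
            if rec.voice is not None and not info.has_voice:
                flag(pid, "modality_mismatch", f"protocol {pid} does not carry voice")
            if rec.voice is not None and rec.voice.channels != P.MFCC_CHANNELS:
                flag(pid, "channel_mismatch",
                     f"voice has {rec.voice.channels} channels, expected {P.MFCC_CHANNELS}")

        # same subject+protocol: all cameras record simultaneously, equal F
        frame_counts = {
            seq.frames for rec in recs for seq in rec.landmarks.values()
        }
        if len(frame_counts) > 1:
            flag(pid, "frame_mismatch",
                 f"cameras disagree on frame count: {sorted(frame_counts)}")

        for rec in recs:
            for part, seq in rec.landmarks.items():
                params = config.staticizer.get(part)
                if params is not None and is_outlier(seq.frames, params):
                    flag(pid, "length_outlier",
                         f"{part} sequence of {seq.frames} frames outside "
                         f"[{params.s}, {params.output_frames}]")
    return ValidationReport(session.subject_id, tuple(violations), usable)
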