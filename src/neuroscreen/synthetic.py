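"""Synthetic cohort generator emulating the examination-room data structure.

Produces subject sessions with the real dataset's shape — 15 protocols with
their modality assignments, four-camera simultaneous recording (equal frame
counts per protocol), variable recording lengths matching the published
per-protocol statistics, class imbalance, uncertain labels with the
corresponding payload dropped, and two recruiting sites — with disease
effects planted on top of healthy-control baseline motion.

Trajectory realism is deliberately minimal (random-phase sinusoid mixtures,
triangle-wave walking drift, smooth MFCC channel trajectories): the point is
pipeline correctness and planted-signal recovery with known ground truth,
not biomechanics.  Disease archetypes follow clinical salience: the
Parkinson's effect loads on rest tremor (4-6 Hz), facial hypomimia and
slowed movement; the stroke effect loads on lateral motion asymmetry,
slowing and voice perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import protocols as P
from .data_model import (
    Camera,
    Disease,
    LandmarkSequence,
    PipelineConfig,
    ProtocolLabel,
    ProtocolRecording,
    Site,
    SubjectSession,
    VoiceFeatureSequence,
)
from .staticizer import PART_PARAMS, StaticizerParams

#: baseline coordinate scale of the synthetic scene (pixel-like units)
SCENE_SCALE = 100.0
#: per-frame white measurement noise on landmark coordinates
MICRO_NOISE_SIGMA = 0.5
#: baseline voluntary-motion amplitude
MOTION_AMPLITUDE = 5.0


@dataclass(frozen=True)
class EffectModel:
    """Planted disease-effect parameters driving the generator.

    All-zero (and slowdown 1, expression 0) means distributionally identical
    to a healthy control.
    """

    tremor_amplitude: float = 0.0      # coordinate units
    tremor_frequency: float = 5.0      # Hz
    slowdown_factor: float = 1.0       # >= 1, stretches motion duration
    hypomimia_factor: float = 0.0      # [0,1], damps face excursions
    gait_asymmetry: float = 0.0        # [0,1], damps left-side body motion
    voice_effect: float = 0.0          # MFCC perturbation scale
    expression_prob: float = 0.9       # P(a given protocol expresses the effect)

    def __post_init__(self) -> None:
        if self.tremor_amplitude < 0 or self.voice_effect < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.slowdown_factor < 1.0:
            raise ValueError("slowdown_factor must be >= 1")
        for name in ("hypomimia_factor", "gait_asymmetry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.expression_prob <= 1.0:
            raise ValueError("expression_prob must lie in [0, 1]")

    @property
    def is_null(self) -> bool:
        return (
            self.tremor_amplitude == 0.0
            and self.slowdown_factor == 1.0
            and self.hypomimia_factor == 0.0
            and self.gait_asymmetry == 0.0
            and self.voice_effect == 0.0
        )

    def affects_part(self, part: str) -> bool:
        moves = self.tremor_amplitude > 0 or self.slowdown_factor > 1
        if part == P.BODY:
            return moves or self.gait_asymmetry > 0
        if part == P.FACE:
            return moves or self.hypomimia_factor > 0
        if part == P.HAND:
            return moves
        raise ValueError(part)

    def affects_protocol(self, protocol_id: int) -> bool:
        info = P.PROTOCOLS[protocol_id]
        if info.has_voice:
            return self.voice_effect > 0
        return any(self.affects_part(p) for p in info.landmark_parts)


def null_effects() -> EffectModel:
    return EffectModel(expression_prob=0.0)


def pd_effects(strength: float = 1.0) -> EffectModel:
    """Parkinsonian archetype: 5 Hz rest tremor at 5x the measurement noise,
    hypomimia, generalized slowing, mild voice monotony."""
    return EffectModel(
        tremor_amplitude=5.0 * MICRO_NOISE_SIGMA * strength,
        tremor_frequency=5.0,
        slowdown_factor=1.0 + 0.5 * strength,
        hypomimia_factor=min(1.0, 0.6 * strength),
        voice_effect=0.5 * strength,
    )


def stroke_effects(strength: float = 1.0) -> EffectModel:
    """Stroke archetype: lateral asymmetry, slowed gait, slurred voice."""
    return EffectModel(
        slowdown_factor=1.0 + 0.4 * strength,
        gait_asymmetry=min(1.0, 0.6 * strength),
        voice_effect=1.0 * strength,
    )


DEFAULT_EFFECTS = {
    Disease.HC: None,
    Disease.STROKE: stroke_effects(),
    Disease.PD: pd_effects(),
}


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


def _default_uncertain_rates() -> dict[int, float]:
    rates = {}
    for pid, info in P.PROTOCOLS.items():
        n = info.n_normal + info.n_abnormal + info.n_uncertain
        rates[pid] = info.n_uncertain / n
    return rates


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    Defaults mirror the source cohort: prevalence 125/574 with patients split
    62 stroke / 63 PD, stroke subjects recruited at KUAH and Parkinsonian
    subjects at SUSH, healthy controls split 205/449 toward KUAH, uncertain
    labels at the per-protocol observed rates, recording lengths lognormal
    with the per-protocol published mean/std (clipped to the staticizer's
    admissible range), 30 fps.
    """

    n_subjects: int = 200
    prevalence: float = 125 / 574
    stroke_fraction: float = 62 / 125          # of patients
    hc_kuah_fraction: float = 205 / 449
    uncertain_rates: dict[int, float] = field(default_factory=_default_uncertain_rates)
    staticizer: dict[str, StaticizerParams] = field(
        default_factory=lambda: dict(PART_PARAMS)
    )
    cameras: tuple[Camera, ...] = (Camera.CENTER, Camera.LEFT)
    fps: float = 30.0
    length_scale: float = 1.0   # shrinks published durations for desk-scale runs

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")

    @classmethod
    def tiny(cls, n_subjects: int = 60, **overrides) -> "CohortSpec":
        from .staticizer import tiny_part_params

        defaults = dict(
            n_subjects=n_subjects,
            staticizer=tiny_part_params(),
            length_scale=0.08,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def admissible_range(self, protocol_id: int) -> tuple[int, int]:
        """[min, max] frame count admissible for every part of the protocol."""
        info = P.PROTOCOLS[protocol_id]
        if info.has_voice:
            lo = max(2, int(round(0.5 * self.fps * self.length_scale * 10)))
            return lo, 10 * lo
        los = [self.staticizer[p].s for p in info.landmark_parts]
        his = [self.staticizer[p].output_frames for p in info.landmark_parts]
        return max(los), min(his)

    def sample_length(self, protocol_id: int, rng: np.random.Generator) -> int:
        info = P.PROTOCOLS[protocol_id]
        mean = info.mean_s * self.fps * self.length_scale
        std = info.std_s * self.fps * self.length_scale
        mu = np.log(mean**2 / np.sqrt(std**2 + mean**2))
        sigma = np.sqrt(np.log(1.0 + (std / mean) ** 2))
        lo, hi = self.admissible_range(protocol_id)
        return int(np.clip(round(rng.lognormal(mu, sigma)), lo, hi))


# ---------------------------------------------------------------------------
# Baseline (healthy-control) motion
# ---------------------------------------------------------------------------


def _template(part: str, rng: np.random.Generator) -> np.ndarray:
    """Static joint layout for one part: canonical pose + per-subject jitter."""
    j = P.JOINT_COUNTS[part]
    if part == P.BODY:
        base = np.array([
            (0.0, 1.0),
            (-0.35, 0.75), (0.35, 0.75),
            (-0.45, 0.45), (0.45, 0.45),
            (-0.5, 0.15), (0.5, 0.15),
            (-0.2, 0.0), (0.2, 0.0),
            (-0.22, -0.5), (0.22, -0.5),
            (-0.25, -1.0), (0.25, -1.0),
        ])
    elif part == P.FACE:
        theta = np.linspace(0, 2 * np.pi, j, endpoint=False)
        base = np.column_stack([np.cos(theta), 0.8 * np.sin(theta)])
    else:  # two hands side by side
        fingers = []
        for hand, x0 in ((0, -0.8), (1, 0.4)):
            pts = [(x0, 0.0)]
            for f in range(5):
                for k in range(1, 5):
                    pts.append((x0 + 0.08 * f, 0.1 * k))
            fingers.append(np.array(pts))
        base = np.vstack(fingers)
    jitter = rng.normal(0.0, 0.03, size=base.shape)
    return (base + jitter) * SCENE_SCALE


def _sinusoid_mixture(frames: int, n_components: int, freq_range, fps: float,
                      rng: np.random.Generator) -> np.ndarray:
    t = np.arange(frames) / fps
    out = np.zeros(frames)
    for _ in range(n_components):
        f = rng.uniform(*freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.uniform(0.4, 1.0) * np.sin(2 * np.pi * f * t + phase)
    return out / max(n_components, 1)


def _baseline_trajectory(part: str, protocol_id: int, frames: int, fps: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency HC motion for one part: (F, J, 2)."""
    template = _template(part, rng)
    j = template.shape[0]
    arr = np.broadcast_to(template, (frames, j, 2)).copy()
    # voluntary motion: per-joint low-frequency sinusoid mixture
    for joint in range(j):
        for c in range(2):
            arr[:, joint, c] += MOTION_AMPLITUDE * _sinusoid_mixture(
                frames, 2, (0.2, 1.2), fps, rng
            )
    info = P.PROTOCOLS[protocol_id]
    if part == P.BODY and "Walking" in info.description:
        # out-and-back drift along x: triangle wave over the recording
        half = frames // 2
        drift = np.concatenate([
            np.linspace(0.0, 1.0, half),
            np.linspace(1.0, 0.0, frames - half),
        ])
        arr[:, :, 0] += 40.0 * SCENE_SCALE / 100.0 * drift[:, None]
    if part == P.FACE:
        # protocol-specific excursion: eye region for eye/forehead tasks,
        # mouth region for the mouth/tongue tasks
        if protocol_id in (1, 2, 3, 4):
            region = np.arange(36, 48)
        else:
            region = np.arange(48, 68)
        excursion = MOTION_AMPLITUDE * np.abs(
            _sinusoid_mixture(frames, 1, (0.3, 0.8), fps, rng)
        )
        arr[:, region, 1] += excursion[:, None]
    arr += rng.normal(0.0, MICRO_NOISE_SIGMA, size=arr.shape)
    return arr


def _baseline_mfcc(frames: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-channel MFCC trajectories + white noise: (F, 25)."""
    base = rng.normal(0.0, 3.0, size=P.MFCC_CHANNELS)
    arr = np.empty((frames, P.MFCC_CHANNELS))
    t = np.arange(frames)
    for c in range(P.MFCC_CHANNELS):
        f = rng.uniform(0.005, 0.05)
        phase = rng.uniform(0, 2 * np.pi)
        arr[:, c] = base[c] + 1.0 * np.sin(2 * np.pi * f * t + phase)
    arr += rng.normal(0.0, 0.3, size=arr.shape)
    return arr


#: left-side body joint indices (shoulder, elbow, wrist, hip, knee, ankle)
_LEFT_BODY = np.array([1, 3, 5, 7, 9, 11])


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------


def _resample_time(arr: np.ndarray, new_frames: int) -> np.ndarray:
    old = arr.shape[0]
    if new_frames == old:
        return arr.copy()
    t_new = np.linspace(0.0, old - 1.0, new_frames)
    t_old = np.arange(old)
    flat = arr.reshape(old, -1)
    out = np.empty((new_frames, flat.shape[1]))
    for k in range(flat.shape[1]):
        out[:, k] = np.interp(t_new, t_old, flat[:, k])
    return out.reshape(new_frames, *arr.shape[1:])


def _apply_landmark_effects(arr: np.ndarray, part: str, effects: EffectModel,
                            fps: float, rng: np.random.Generator,
                            max_frames: int | None = None) -> np.ndarray:
    frames = arr.shape[0]
    if effects.slowdown_factor > 1.0:
        new_frames = int(round(frames * effects.slowdown_factor))
        if max_frames is not None:
            new_frames = min(new_frames, max_frames)
        arr = _resample_time(arr, new_frames)
        frames = new_frames
    if part == P.FACE and effects.hypomimia_factor > 0.0:
        mean_pose = arr.mean(axis=0, keepdims=True)
        arr = mean_pose + (arr - mean_pose) * (1.0 - effects.hypomimia_factor)
    if part == P.BODY and effects.gait_asymmetry > 0.0:
        mean_pose = arr[:, _LEFT_BODY].mean(axis=0, keepdims=True)
        arr = arr.copy()
        arr[:, _LEFT_BODY] = mean_pose + (arr[:, _LEFT_BODY] - mean_pose) * (
            1.0 - effects.gait_asymmetry
        )
    if effects.tremor_amplitude > 0.0:
        t = np.arange(frames) / fps
        j = arr.shape[1]
        phases = rng.uniform(0, 2 * np.pi, size=(j, 2))
        tremor = effects.tremor_amplitude * np.sin(
            2 * np.pi * effects.tremor_frequency * t[:, None, None] + phases
        )
        arr = arr + tremor
    return arr


def _apply_voice_effects(arr: np.ndarray, effects: EffectModel,
                         rng: np.random.Generator) -> np.ndarray:
    if effects.voice_effect <= 0.0:
        return arr
    frames, channels = arr.shape
    t = np.arange(frames)
    f = rng.uniform(0.01, 0.04)
    weights = rng.normal(0.0, 1.0, size=channels)
    modulation = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    out = arr + effects.voice_effect * modulation[:, None] * weights[None, :]
    out = out + rng.normal(0.0, 0.5 * effects.voice_effect, size=out.shape)
    return out


def apply_effects(recording: ProtocolRecording, effects: EffectModel,
                  rng: np.random.Generator, fps: float = 30.0,
                  max_frames: int | None = None) -> ProtocolRecording:
    """Plant one subject's disease effects into a recording.

    A null effect model returns the recording unchanged.  Slowdown stretches
    the time axis (clipped to ``max_frames`` when given); tremor adds a
    sinusoid at the tremor frequency to every joint; hypomimia/asymmetry damp
    excursions; the voice effect perturbs the MFCC table.
    """
    if effects.is_null:
        return recording
    landmarks = {}
    for part, seq in recording.landmarks.items():
        arr = _apply_landmark_effects(seq.array, part, effects, seq.fps, rng,
                                      max_frames=max_frames)
        landmarks[part] = LandmarkSequence(part=part, array=arr, fps=seq.fps)
    voice = recording.voice
    if voice is not None:
        voice = VoiceFeatureSequence(_apply_voice_effects(voice.array, effects, rng))
    return ProtocolRecording(recording.protocol_id, recording.camera,
                             landmarks, voice)


# ---------------------------------------------------------------------------
# Recording / session / cohort generation
# ---------------------------------------------------------------------------


def _camera_view(arr: np.ndarray, camera: Camera,
                 rng: np.random.Generator) -> np.ndarray:
    """Affine-perturbed view of the shared underlying trajectory."""
    if camera is Camera.CENTER:
        return arr
    angle = rng.uniform(-0.15, 0.15)
    scale = rng.uniform(0.9, 1.1)
    offset = rng.uniform(-10.0, 10.0, size=2)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return arr @ rot.T * scale + offset


def generate_hc_recording(protocol_id: int, camera: Camera, length: int,
                          rng: np.random.Generator,
                          fps: float = 30.0) -> ProtocolRecording:
    """One healthy-control recording for one (protocol, camera) pair."""
    info = P.PROTOCOLS[protocol_id]
    landmarks = {}
    for part in info.landmark_parts:
        arr = _baseline_trajectory(part, protocol_id, length, fps, rng)
        arr = _camera_view(arr, camera, rng)
        landmarks[part] = LandmarkSequence(part=part, array=arr, fps=fps)
    voice = None
    if info.has_voice:
        voice = VoiceFeatureSequence(_baseline_mfcc(length, rng))
    return ProtocolRecording(protocol_id, camera, landmarks, voice)


def generate_session(
    subject_id: str,
    disease: Disease,
    spec: CohortSpec,
    effects: EffectModel | None,
    site: Site,
    rng: np.random.Generator,
) -> SubjectSession:
    """One subject: per-protocol recordings, expression-gated effects, labels."""
    labels: list[ProtocolLabel] = []
    recordings: list[ProtocolRecording] = []
    for pid in P.PROTOCOL_IDS:
        info = P.PROTOCOLS[pid]
        length = spec.sample_length(pid, rng)
        lo, hi = spec.admissible_range(pid)

        expressed = (
            effects is not None
            and not effects.is_null
            and effects.affects_protocol(pid)
            and rng.random() < effects.expression_prob
        )
        label = ProtocolLabel.ABNORMAL if expressed else ProtocolLabel.NORMAL

        uncertain = rng.random() < spec.uncertain_rates.get(pid, 0.0)
        if uncertain:
            label = ProtocolLabel.UNCERTAIN

        # one underlying trajectory; cameras see affine-perturbed copies
        if info.has_voice:
            cams = (Camera.CENTER,)
        else:
            cams = spec.cameras
        base = generate_hc_recording(pid, Camera.CENTER, length, rng, spec.fps)
        if expressed:
            base = apply_effects(base, effects, rng, spec.fps, max_frames=hi)
        for camera in cams:
            landmarks = {
                part: LandmarkSequence(
                    part=part,
                    array=_camera_view(seq.array, camera, rng),
                    fps=seq.fps,
                )
                for part, seq in base.landmarks.items()
            }
            voice = base.voice
            if uncertain:
                # occluded/unusable payload: drop face if present, else all
                if P.FACE in landmarks:
                    landmarks.pop(P.FACE)
                else:
                    landmarks = {}
                    voice = None
            recordings.append(
                ProtocolRecording(pid, camera, landmarks, voice)
            )
        labels.append(label)
    return SubjectSession(
        subject_id=subject_id,
        disease_label=disease,
        protocol_labels=tuple(labels),
        recordings=tuple(recordings),
        site=site,
    )


def generate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    effects: dict[Disease, EffectModel | None] | None = None,
) -> list[SubjectSession]:
    """A full cohort; disease mix follows the prevalence, sites follow the
    per-disease recruiting hospitals."""
    effects = DEFAULT_EFFECTS if effects is None else effects
    n = spec.n_subjects
    n_patients = int(round(n * spec.prevalence))
    n_stroke = int(round(n_patients * spec.stroke_fraction))
    n_pd = n_patients - n_stroke
    if min(n_stroke, n_pd, n - n_patients) < 1:
        raise ValueError(
            f"infeasible spec: n={n}, prevalence={spec.prevalence} yields "
            f"{n_stroke} stroke / {n_pd} PD / {n - n_patients} HC subjects"
        )
    diseases = (
        [Disease.STROKE] * n_stroke + [Disease.PD] * n_pd
        + [Disease.HC] * (n - n_patients)
    )
    rng.shuffle(diseases)
    sessions = []
    for i, disease in enumerate(diseases):
        if disease is Disease.STROKE:
            site = Site.KUAH
        elif disease is Disease.PD:
            site = Site.SUSH
        else:
            site = Site.KUAH if rng.random() < spec.hc_kuah_fraction else Site.SUSH
        sessions.append(
            generate_session(f"S{i:04d}", disease, spec, effects[disease], site, rng)
        )
    return sessions


# ---------------------------------------------------------------------------
# Pretraining proxy corpora
# ---------------------------------------------------------------------------


def make_motion_classification_task(part: str, n_samples: int, frames: int,
                                    rng: np.random.Generator, fps: float = 30.0):
    """3-class proxy task (static / oscillating / drifting trajectories) for
    landmark-encoder pretraining; separable by construction."""
    from .encoders import PretrainTask
    from .preprocessing import dynamic_representation, normalize_landmarks

    inputs, targets = [], []
    for _ in range(n_samples):
        cls = rng.integers(3)
        arr = np.broadcast_to(_template(part, rng), (frames, P.JOINT_COUNTS[part], 2)).copy()
        t = np.arange(frames) / fps
        if cls == 1:  # oscillating
            arr += 5.0 * np.sin(2 * np.pi * rng.uniform(2, 6) * t)[:, None, None]
        elif cls == 2:  # drifting
            arr[:, :, 0] += np.linspace(0, 30.0, frames)[:, None]
        arr += rng.normal(0.0, MICRO_NOISE_SIGMA, size=arr.shape)
        seq = normalize_landmarks(LandmarkSequence(part=part, array=arr, fps=fps))
        inputs.append(dynamic_representation(seq))
        targets.append(cls)
    return PretrainTask(np.stack(inputs), np.array(targets), "classification")


def make_speaker_task(n_speakers: int, n_samples: int, frames: int,
                      rng: np.random.Generator):
    """Speaker-identification proxy task for voice-encoder pretraining: each
    speaker is a distinct base MFCC profile."""
    from .encoders import PretrainTask

    profiles = rng.normal(0.0, 3.0, size=(n_speakers, P.MFCC_CHANNELS))
    inputs, targets = [], []
    for _ in range(n_samples):
        spk = int(rng.integers(n_speakers))
        arr = _baseline_mfcc(frames, rng)
        arr = arr - arr.mean(axis=0, keepdims=True) + profiles[spk]
        inputs.append(arr)
        targets.append(spk)
    return PretrainTask(np.stack(inputs), np.array(targets), "classification")
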