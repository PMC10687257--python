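"""Landmark normalization, position+velocity stacking, augmentation, MFCC sizing.

Raw trajectories live in camera pixel units at whatever scale the subject
happened to occupy, so landmark sequences are centred and scaled before
encoding.  Augmentation draws one similarity transform per sequence (rotation
about the centroid, scaling, translation by a fraction of the coordinate
extent) and applies it to every frame — the transform a different camera
placement would have produced.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .data_model import AugmentationRanges, LandmarkSequence, VoiceFeatureSequence


def normalize_landmarks(seq: LandmarkSequence) -> LandmarkSequence:
    """Centre on the per-sequence mean; scale the RMS radius to 1.

    Degenerate sequences (all joints at one constant point) are centred but
    left unscaled.  Idempotent, and invariant to input translation/scaling.
    """
    arr = seq.array
    center = arr.reshape(-1, 2).mean(axis=0)
    centered = arr - center
    rms = float(np.sqrt(np.mean(np.sum(centered ** 2, axis=2))))
    # all-equal sequences leave only float residue after centring; don't scale
    if rms > 1e-9 * max(1.0, float(np.abs(arr).max())):
        centered = centered / rms
    else:
        centered = np.zeros_like(arr)
    return replace(seq, array=centered)


def dynamic_representation(seq: LandmarkSequence) -> np.ndarray:
    """Stack positions and frame-difference velocities: F x J x 4.

    v_t = p_t - p_{t-1} with v_1 = 0; needs at least two frames.
    """
    arr = seq.array
    if arr.shape[0] < 2:
        raise ValueError("dynamic representation needs at least 2 frames")
    vel = np.zeros_like(arr)
    vel[1:] = arr[1:] - arr[:-1]
    return np.concatenate([arr, vel], axis=2)


def apply_similarity(
    seq: LandmarkSequence,
    angle_deg: float,
    scale: float,
    shift_frac: np.ndarray,
) -> LandmarkSequence:
    """Rotate/scale/translate every frame by one fixed similarity transform.

    The rotation centre and the extent used to convert the fractional
    translation into coordinate units are taken from the *first frame*, so
    the transform is a pure frame-wise map: it commutes bit-exactly with any
    frame-selection operation (in particular the staticizer, which always
    keeps frame 1).
    """
    angle = math.radians(angle_deg)
    shift_frac = np.asarray(shift_frac, dtype=float)
    if angle == 0.0 and scale == 1.0 and not shift_frac.any():
        return seq
    arr = seq.array
    first = arr[0]
    center = first.mean(axis=0)
    extent = first.max(axis=0) - first.min(axis=0)
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    out = (arr - center) @ rot.T * scale + center + shift_frac * extent
    return replace(seq, array=out)


def augment_landmarks(
    seq: LandmarkSequence,
    ranges: AugmentationRanges,
    rng: np.random.Generator,
) -> LandmarkSequence:
    """One random rotation/scale/translation applied to every frame and joint.

    Deterministic for a given generator state; zero-width identity ranges
    return the input bit-exactly.
    """
    lo, hi = ranges.rotation_deg
    angle_deg = rng.uniform(lo, hi)
    lo, hi = ranges.scale_pct
    scale = rng.uniform(lo, hi) / 100.0
    lo, hi = ranges.translation_pct
    shift_frac = rng.uniform(lo, hi, size=2) / 100.0
    return apply_similarity(seq, angle_deg, scale, shift_frac)


def prepare_mfcc(seq: VoiceFeatureSequence, target_frames: int) -> VoiceFeatureSequence:
    """Fix the MFCC table length: truncate long inputs, tile short ones.

    A short recording is repeated periodically (period = its own length) and
    cut at ``target_frames``, so the fixed-size sample is always filled with
    real speech frames rather than padding.
    """
    if target_frames <= 0:
        raise ValueError("target_frames must be positive")
    arr = seq.array
    frames = arr.shape[0]
    if frames == target_frames:
        return seq
    if frames > target_frames:
        return replace(seq, array=arr[:target_frames].copy())
    reps = -(-target_frames // frames)
    return replace(seq, array=np.tile(arr, (reps, 1))[:target_frames])
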