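"""Frame-length staticizer: variable-length sequences to a fixed N*S frames.

Fixed-input networks need equal-length sequences, but subjects take different
times to perform the same examination.  Subsampling drops frames (and with
them the momentary tremors that matter for screening); zero-padding makes some
samples padding-dominated.  The staticizer instead cuts the input into N
overlapping segments of S frames whose starts are spread evenly across the
sequence,

    I_i = floor((i - 1) * (F - S) / (N - 1)) + 1,   i = 1..N   (1-based),

and concatenates the segments on the frame axis.  Every input frame appears in
the output (coverage) whenever F <= N*S, the output length is always exactly
N*S, and when F == N*S the map is the identity.  The pipeline treats lengths
outside [S, N*S] as outliers (see :func:`is_outlier`) and excludes them
upstream; the operator itself only requires F >= S.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .protocols import BODY, FACE, HAND


@dataclass(frozen=True)
class StaticizerParams:
    """Number of segments ``n`` and frames per segment ``s``."""

    n: int
    s: int

    def __post_init__(self) -> None:
        if self.n < 1 or self.s < 1:
            raise ValueError(f"N and S must be >= 1, got N={self.n}, S={self.s}")

    @property
    def output_frames(self) -> int:
        """F' = N * S."""
        return self.n * self.s


#: per-part presets: body 4500 frames (N=150, S=30), face 1200 (40, 30),
#: hand 1500 (50, 30)
PART_PARAMS = {
    BODY: StaticizerParams(150, 30),
    FACE: StaticizerParams(40, 30),
    HAND: StaticizerParams(50, 30),
}


def tiny_part_params(scale: int = 10) -> dict[str, StaticizerParams]:
    """Shrunken presets (same N ratios, S=scale) for desk-scale runs."""
    return {
        BODY: StaticizerParams(15, scale),
        FACE: StaticizerParams(4, scale),
        HAND: StaticizerParams(5, scale),
    }


def is_outlier(frames: int, params: StaticizerParams) -> bool:
    """True iff a sequence of this length cannot be staticized (F > N*S or F < S)."""
    return frames > params.output_frames or frames < params.s


def segment_starts(frames: int, params: StaticizerParams) -> np.ndarray:
    """1-based starting frames of the N segments.

    Starts are nondecreasing, begin at 1 and end at F - S + 1, so the segments
    jointly cover every input frame.  N == 1 degenerates to the single start
    ``[1]`` (the first S frames).
    """
    n, s = params.n, params.s
    if frames < s:
        raise ValueError(f"input shorter than segment: F={frames} < S={s}")
    if n == 1:
        return np.array([1], dtype=np.int64)
    i = np.arange(n, dtype=np.int64)
    return i * (frames - s) // (n - 1) + 1


def staticize(seq, params: StaticizerParams):
    """Map a sequence object (or raw frames-first array) to exactly N*S frames.

    Accepts a ``LandmarkSequence``/``VoiceFeatureSequence`` (anything exposing
    a frames-first array via ``.array`` and supporting ``dataclasses.replace``)
    or a plain ndarray whose leading axis is frames.
    """
    arr = seq.array if hasattr(seq, "array") else np.asarray(seq)
    out = _staticize_array(arr, params)
    if hasattr(seq, "array"):
        return replace(seq, array=out)
    return out


def _staticize_array(arr: np.ndarray, params: StaticizerParams) -> np.ndarray:
    frames = arr.shape[0]
    if frames < params.s:
        raise ValueError(f"input shorter than segment: F={frames} < S={params.s}")
    if frames == params.output_frames:
        return arr.copy()
    starts0 = segment_starts(frames, params) - 1  # 0-based
    idx = (starts0[:, None] + np.arange(params.s)[None, :]).ravel()
    return arr[idx]
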