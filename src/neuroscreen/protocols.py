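"""The 15 examination protocols: modality map and cohort-level statistics.

This table is the single source of truth for which modalities (body, face,
hand landmarks; voice) each protocol produces.  Every other module queries it
instead of hard-coding protocol numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

BODY = "body"
FACE = "face"
HAND = "hand"
VOICE = "voice"

LANDMARK_PARTS = (BODY, FACE, HAND)
MODALITIES = (BODY, FACE, HAND, VOICE)

#: joints per landmark part (13 body, 68 face, 21 per hand x 2 hands)
JOINT_COUNTS = MappingProxyType({BODY: 13, FACE: 68, HAND: 42})

#: MFCC channels per voice frame
MFCC_CHANNELS = 25


@dataclass(frozen=True)
class ProtocolInfo:
    """One examination protocol and what gets extracted from its recording."""

    protocol_id: int
    description: str
    modalities: tuple[str, ...]
    #: mean/std/max recording length in seconds at 30 fps
    mean_s: float
    std_s: float
    max_s: float
    #: observed label frequencies (normal, abnormal, uncertain) in the source cohort
    n_normal: int
    n_abnormal: int
    n_uncertain: int

    @property
    def landmark_parts(self) -> tuple[str, ...]:
        return tuple(m for m in self.modalities if m in LANDMARK_PARTS)

    @property
    def has_voice(self) -> bool:
        return VOICE in self.modalities


_TABLE = (
    ProtocolInfo(1, "Standing still and moving eyes up and down, left and right",
                 (BODY, FACE), 12.6, 4.2, 35.0, 483, 19, 3),
    ProtocolInfo(2, "Standing still and moving eyes up and down, left and right",
                 (BODY, FACE), 12.1, 4.1, 67.5, 483, 19, 3),
    ProtocolInfo(3, "Looking up while standing still, wrinkling forehead",
                 (FACE,), 5.5, 2.1, 25.0, 503, 2, 0),
    ProtocolInfo(4, "Closing eyes tightly",
                 (FACE,), 5.8, 2.0, 18.0, 475, 29, 1),
    ProtocolInfo(5, "Showing teeth while raising the corners of mouth",
                 (FACE,), 4.6, 2.0, 35.5, 450, 25, 30),
    ProtocolInfo(6, "Opening mouth",
                 (FACE,), 4.2, 1.7, 28.5, 476, 1, 28),
    ProtocolInfo(7, "Sticking tongue out",
                 (FACE,), 4.7, 1.8, 19.5, 476, 1, 28),
    ProtocolInfo(8, "Making 'ah' sound",
                 (VOICE,), 3.8, 2.3, 31.0, 418, 85, 2),
    ProtocolInfo(9, "Speaking a sentence 1",
                 (VOICE,), 7.3, 2.4, 38.0, 448, 54, 3),
    ProtocolInfo(10, "Speaking a sentence 2",
                 (VOICE,), 7.5, 1.8, 20.0, 447, 53, 5),
    ProtocolInfo(11, "Putting both hands at chest level while palms facing the floor",
                 (HAND,), 13.4, 2.3, 47.5, 482, 21, 2),
    ProtocolInfo(12, "Pointing nose alternately with both index fingers",
                 (FACE, HAND), 13.0, 4.3, 39.5, 480, 20, 5),
    ProtocolInfo(13, "Contacting tips of the thumb and index finger of both hands",
                 (FACE, HAND), 23.3, 7.5, 47.0, 399, 87, 22),
    ProtocolInfo(14, "Walking through a straight line and returning back",
                 (BODY,), 33.3, 9.4, 141.0, 411, 90, 4),
    ProtocolInfo(15, "Walking through a straight line while outstretching both arms "
                     "and returning back",
                 (BODY,), 29.1, 10.0, 124.5, 458, 39, 8),
)

PROTOCOLS: MappingProxyType[int, ProtocolInfo] = MappingProxyType(
    {p.protocol_id: p for p in _TABLE}
)

PROTOCOL_IDS = tuple(sorted(PROTOCOLS))
N_PROTOCOLS = len(PROTOCOL_IDS)

#: protocols whose recordings are landmark trajectories / voice features
LANDMARK_PROTOCOLS = tuple(p for p in PROTOCOL_IDS if PROTOCOLS[p].landmark_parts)
VOICE_PROTOCOLS = tuple(p for p in PROTOCOL_IDS if PROTOCOLS[p].has_voice)


def modalities_of(protocol_id: int) -> tuple[str, ...]:
    """Modalities extracted for one protocol (raises KeyError for bad ids)."""
    return PROTOCOLS[protocol_id].modalities
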