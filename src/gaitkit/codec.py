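"""Fused pressure-word codec.

The insole carries eight force sensors, each reporting a 2-bit pressing
level in {0, 1, 2, 3}.  The firmware packs the eight levels into a single
16-bit word before transmission: Sensor 1 (first-metatarsal area) occupies
the two most significant bits, Sensor 8 (heel edge) the two least
significant.  A word of 0 therefore means "all sensors off" (foot in the
air) and a word of 1 means "only Sensor 8, slightly pressed" — the
late-swing artifact the segmentation threshold is designed to absorb.
"""

from __future__ import annotations

from collections.abc import Sequence

N_SENSORS = 8
MAX_WORD = (1 << (2 * N_SENSORS)) - 1  # 65535


def encode_pressure(levels: Sequence[int]) -> int:
    """Pack eight 2-bit sensor levels into one 16-bit pressure word.

    Parameters
    ----------
    levels
        Exactly eight integers, each in {0, 1, 2, 3}, ordered Sensor 1
        first.  Sensor 1 lands in bits 15-14, Sensor 8 in bits 1-0.

    Returns
    -------
    int
        The fused word in [0, 65535].
    """
    levels = list(levels)
    if len(levels) != N_SENSORS:
        raise ValueError(f"expected {N_SENSORS} sensor levels, got {len(levels)}")
    word = 0
    for i, level in enumerate(levels):
        if not isinstance(level, (int,)) or isinstance(level, bool):
            raise ValueError(f"sensor {i + 1} level must be an integer, got {level!r}")
        if not 0 <= level <= 3:
            raise ValueError(f"sensor {i + 1} level {level} outside {{0,1,2,3}}")
        word = (word << 2) | level
    return word


def decode_pressure(word: int) -> list[int]:
    """Unpack a 16-bit pressure word into eight 2-bit sensor levels.

    Exact inverse of :func:`encode_pressure` for every word in [0, 65535].
    """
    if not isinstance(word, (int,)) or isinstance(word, bool):
        raise ValueError(f"pressure word must be an integer, got {word!r}")
    if not 0 <= word <= MAX_WORD:
        raise ValueError(f"pressure word {word} outside [0, {MAX_WORD}]")
    return [(word >> (2 * (N_SENSORS - 1 - i))) & 0b11 for i in range(N_SENSORS)]
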