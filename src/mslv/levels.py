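"""Vertebral level labels and ordinal arithmetic.

Levels are identified by their clinical labels (``C7``, ``T1`` ... ``T12``,
``L1`` ... ``L5``, ``S1``) and ordered cranial to caudal.  All comparisons in
the package go through the ordinal index so that "cranial to" / "caudal to"
relations are unambiguous.
"""

from __future__ import annotations

from .errors import LevelError

#: Canonical cranial-to-caudal order of every level the package knows about.
ORDER: tuple[str, ...] = (
    "C7",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "S1",
)

_INDEX = {lvl: i for i, lvl in enumerate(ORDER)}

#: Levels carried by a coronal (PA) film record: C7 through L5.
CORONAL_LEVELS: tuple[str, ...] = ORDER[:-1]

#: Levels carried by a sagittal film record: T1 through S1.
SAGITTAL_LEVELS: tuple[str, ...] = ORDER[1:]


def index(level: str) -> int:
    """Ordinal index of *level* (0 = C7, increasing caudally)."""
    try:
        return _INDEX[level]
    except KeyError:
        raise LevelError(f"unknown vertebral level {level!r}") from None


def is_cranial(a: str, b: str) -> bool:
    """True when level *a* is strictly cranial to level *b*."""
    return index(a) < index(b)


def shift(level: str, n: int) -> str:
    """Level *n* steps caudal to *level* (negative *n* = cranial)."""
    i = index(level) + n
    if not 0 <= i < len(ORDER):
        raise LevelError(f"level {level} shifted by {n} leaves the spine")
    return ORDER[i]


def span(upper: str, lower: str) -> tuple[str, ...]:
    """Inclusive cranial-to-caudal run of levels from *upper* to *lower*."""
    i, j = index(upper), index(lower)
    if i > j:
        raise LevelError(f"{upper} is not cranial to {lower}")
    return ORDER[i : j + 1]
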