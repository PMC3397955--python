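"""Canonical naming and enumeration of microsatellite repeat-unit classes.

A repeat-unit class groups every circular permutation (rotation) of a unit
together with every rotation of its reverse complement, and is named by the
alphabetically smallest member under the order A < C < G < T (e.g. the class
AAC contains AAC, ACA, CAA, TTG, TGT and GTT).  Units that are themselves a
whole-number tandem repetition of a shorter unit (``AA``, ``ACAC``) are not
independent classes: they reduce to their primitive root.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

MAX_UNIT_LENGTH = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class InvalidMotifError(ValueError):
    """Raised when a motif is empty, too long, or contains non-ACGT characters."""


def _normalize(motif: str) -> str:
    m = motif.upper()
    if not m:
        raise InvalidMotifError("motif must be non-empty")
    if len(m) > MAX_UNIT_LENGTH:
        raise InvalidMotifError(
            f"motif {m!r} longer than {MAX_UNIT_LENGTH} bases"
        )
    if not _ALPHABET.issuperset(m):
        raise InvalidMotifError(f"motif {m!r} contains non-ACGT characters")
    return m


def reverse_complement(motif: str) -> str:
    """Watson-Crick complement, reversed.  An involution on valid motifs."""
    return _normalize(motif).translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff ``motif`` is not a whole-number (>1) repetition of a shorter unit.

    Uses the doubling criterion: a string is non-primitive exactly when it
    occurs in its own doubling with both flanking characters removed.
    """
    m = _normalize(motif)
    return (m + m).find(m, 1) == len(m)


def primitive_root(motif: str) -> str:
    """Shortest unit whose tandem repetition equals ``motif`` (A for AAAA)."""
    m = _normalize(motif)
    period = (m + m).find(m, 1)
    return m[:period]


def _rotations(m: str) -> list[str]:
    return [m[i:] + m[:i] for i in range(len(m))]


@lru_cache(maxsize=None)
def canonical_name(motif: str) -> str:
    """Alphabetically minimal rotation of a motif or of its reverse complement.

    Non-primitive input is reduced to its primitive root first, so the result
    is always a primitive canonical class name (``AAAA`` -> ``A``).
    """
    m = primitive_root(motif)
    return min(_rotations(m) + _rotations(reverse_complement(m)))


@dataclass(frozen=True)
class CanonicalMotif:
    """A canonical repeat-unit class name together with its unit length."""

    name: str
    unit_length: int

    @classmethod
    def from_motif(cls, motif: str) -> "CanonicalMotif":
        name = canonical_name(motif)
        return cls(name=name, unit_length=len(name))

    def __post_init__(self) -> None:
        if canonical_name(self.name) != self.name:
            raise InvalidMotifError(f"{self.name!r} is not a canonical class name")
        if self.unit_length != len(self.name):
            raise InvalidMotifError(
                f"unit_length {self.unit_length} does not match {self.name!r}"
            )

    def __str__(self) -> str:
        return self.name


@lru_cache(maxsize=None)
def enumerate_classes(k: int) -> tuple[str, ...]:
    """All canonical class names of primitive units of length ``k``, sorted.

    Cardinalities are 2, 4, 10, 33, 102 and 350 for k = 1..6.
    """
    if not 1 <= k <= MAX_UNIT_LENGTH:
        raise InvalidMotifError(f"unit length must be 1..{MAX_UNIT_LENGTH}, got {k}")
    names = {
        canonical_name(m)
        for m in ("".join(p) for p in product("ACGT", repeat=k))
        if is_primitive(m)
    }
    return tuple(sorted(names))


def all_canonical_motifs(max_unit_length: int = MAX_UNIT_LENGTH) -> tuple[str, ...]:
    """Canonical names of every class with unit length <= ``max_unit_length``,
    ordered by unit length then alphabetically (the CSV column order)."""
    out: list[str] = []
    for k in range(1, max_unit_length + 1):
        out.extend(enumerate_classes(k))
    return tuple(out)
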