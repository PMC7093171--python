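"""Motif algebra for microsatellite repeat units.

A repeat unit of length 1-6 defines an equivalence class together with all
its circular permutations (rotations) and the rotations of its reverse
complement: (GT)n, (TG)n, (AC)n and (CA)n runs are all the same biological
repeat read from different phases/strands.  The class representative
("canonical motif") is the lexicographically smallest member of the orbit.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

__all__ = [
    "revcomp",
    "is_primitive",
    "canonical_motif",
    "rotations",
    "canonical_classes",
    "count_canonical_classes",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = set(motif) - _ALPHABET
    if bad:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters: {sorted(bad)}")
    return motif


def is_primitive(motif: str) -> bool:
    """True unless *motif* is a whole-number repetition of a shorter unit.

    ``ACAC`` is (AC)x2 and therefore not primitive; a poly-A run must be
    reported with unit ``A``, never ``AA`` or ``AAA``.
    """
    motif = _validate(motif)
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def rotations(motif: str) -> list[str]:
    """All circular permutations of *motif* (including itself)."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


@lru_cache(maxsize=None)
def canonical_motif(motif: str) -> str:
    """Class representative for a primitive repeat unit.

    Lexicographic minimum over the rotations of *motif* and the rotations of
    its reverse complement.  Constant on each orbit and idempotent.

    Raises
    ------
    ValueError
        If *motif* contains non-ACGT characters, is longer than 6 bp, or is
        not primitive.
    """
    motif = _validate(motif)
    if len(motif) > 6:
        raise ValueError(f"motif {motif!r} longer than 6 bp")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    return min(rotations(motif) + rotations(revcomp(motif)))


@lru_cache(maxsize=None)
def canonical_classes(unit_length: int) -> tuple[str, ...]:
    """Sorted canonical representatives of all primitive motifs of a length."""
    if not 1 <= unit_length <= 6:
        raise ValueError(f"unit_length must be in 1..6, got {unit_length}")
    reps = {
        canonical_motif("".join(m))
        for m in itertools.product("ACGT", repeat=unit_length)
        if is_primitive("".join(m))
    }
    return tuple(sorted(reps))


def count_canonical_classes(unit_length: int) -> int:
    """Number of distinct canonical classes of primitive motifs of a length."""
    return len(canonical_classes(unit_length))
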