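"""Small DNA string utilities shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_dna(seq: str) -> bool:
    return set(seq) <= VALID_BASES


def split_at_ambiguous(seq: str) -> list[str]:
    """Split a sequence at any non-ACGT symbol, returning the clean stretches.

    Uppercases first, so soft-masked (lowercase) bases are kept.
    """
    out: list[str] = []
    current: list[str] = []
    for ch in seq.upper():
        if ch in VALID_BASES:
            current.append(ch)
        elif current:
            out.append("".join(current))
            current = []
    if current:
        out.append("".join(current))
    return out
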